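"""Training-set database, model persistence and benchmark reports.

One HDF5 container holds a training set for one (molecule, method)
combination: per-sample external-potential and 1-rdm matrices (in the
aligned internal frame), energies, forces and dipoles, the conformer
reference geometries, and the sampling plan with its seed.  A JSON
sidecar duplicates the metadata for quick inspection.  Fitted surrogate
models persist into the same kind of container; save/load round-trips
every matrix bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import __version__ as _pkg_version
from .engine import EngineError, MethodSpec, compute_ao_matrices, run_reference
from .frames import align_to_reference
from .geometry import Geometry
from .sampler import SamplePlan, generate_samples, normal_mode_analysis

log = logging.getLogger(__name__)


@dataclass
class TrainingSet:
    """External-potential / 1-rdm training records in the internal frame."""

    spec: MethodSpec
    references: list                       # conformer equilibrium geometries
    ref_index: np.ndarray                  # (N,) conformer of each sample
    coords: list                           # per-sample aligned coords, Å
    potentials: np.ndarray                 # (N, n_ao, n_ao)
    gammas: np.ndarray                     # (N, n_ao, n_ao)
    energies: np.ndarray                   # (N,) Hartree
    forces: np.ndarray | None              # (N, n_atoms, 3) Ha/Bohr, aligned
    dipoles: np.ndarray | None             # (N, 3) Debye, aligned
    plan: dict = field(default_factory=dict)
    engine: str = field(default_factory=lambda: f"rdmlearn-builtin {_pkg_version}")

    @property
    def reference(self) -> Geometry:
        return self.references[0]

    @property
    def n_samples(self) -> int:
        return len(self.energies)

    @property
    def n_ao(self) -> int:
        return self.potentials.shape[1]

    def sample_geometry(self, i: int) -> Geometry:
        ref = self.references[int(self.ref_index[i])]
        return ref.with_coords(self.coords[i])

    def compatible_with(self, other: "TrainingSet") -> bool:
        return (self.spec.to_dict() == other.spec.to_dict()
                and self.n_ao == other.n_ao)

    def merged(self, other: "TrainingSet") -> "TrainingSet":
        if not self.compatible_with(other):
            raise ValueError(
                "cannot merge training sets with different method metadata "
                "or AO dimension"
            )

        def cat(a, b):
            if a is None or b is None:
                return None
            return np.concatenate([np.asarray(a), np.asarray(b)])

        return TrainingSet(
            spec=self.spec,
            references=self.references + other.references,
            ref_index=cat(self.ref_index,
                          other.ref_index + len(self.references)),
            coords=list(self.coords) + list(other.coords),
            potentials=cat(self.potentials, other.potentials),
            gammas=cat(self.gammas, other.gammas),
            energies=cat(self.energies, other.energies),
            forces=cat(self.forces, other.forces),
            dipoles=cat(self.dipoles, other.dipoles),
            plan={"merged": [self.plan, other.plan]},
            engine=self.engine,
        )

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        with h5py.File(path, "w") as f:
            _write_meta(f, {
                "kind": "training_set",
                "spec": self.spec.to_dict(),
                "plan": self.plan,
                "engine": self.engine,
            })
            ref_grp = f.create_group("references")
            for i, ref in enumerate(self.references):
                _write_geometry(ref_grp.create_group(str(i)), ref)
            f["ref_index"] = np.asarray(self.ref_index, dtype=np.int64)
            cg = f.create_group("coords")
            for i, c in enumerate(self.coords):
                cg[str(i)] = np.asarray(c)
            f["potentials"] = self.potentials
            f["gammas"] = self.gammas
            f["energies"] = self.energies
            if self.forces is not None:
                f["forces"] = self.forces
            if self.dipoles is not None:
                f["dipoles"] = self.dipoles
        _write_sidecar(path, {
            "kind": "training_set",
            "spec": self.spec.to_dict(),
            "plan": self.plan,
            "engine": self.engine,
            "n_samples": self.n_samples,
            "n_ao": int(self.n_ao),
        })

    @classmethod
    def load(cls, path) -> "TrainingSet":
        with h5py.File(path, "r") as f:
            meta = _read_meta(f)
            refs = [
                _read_geometry(f["references"][k])
                for k in sorted(f["references"], key=int)
            ]
            coords = [
                f["coords"][k][()] for k in sorted(f["coords"], key=int)
            ]
            return cls(
                spec=MethodSpec.from_dict(meta["spec"]),
                references=refs,
                ref_index=f["ref_index"][()],
                coords=coords,
                potentials=f["potentials"][()],
                gammas=f["gammas"][()],
                energies=f["energies"][()],
                forces=f["forces"][()] if "forces" in f else None,
                dipoles=f["dipoles"][()] if "dipoles" in f else None,
                plan=meta.get("plan", {}),
                engine=meta.get("engine", "unknown"),
            )


def _write_meta(f, meta: dict):
    f.attrs["meta_json"] = json.dumps(meta, sort_keys=True)


def _read_meta(f) -> dict:
    return json.loads(f.attrs["meta_json"])


def _write_geometry(grp, geom: Geometry):
    grp["coords"] = geom.coords
    grp.attrs["symbols"] = ",".join(geom.symbols)
    grp.attrs["charge"] = geom.charge
    grp.attrs["multiplicity"] = geom.multiplicity


def _read_geometry(grp) -> Geometry:
    return Geometry(
        symbols=tuple(grp.attrs["symbols"].split(",")),
        coords=grp["coords"][()],
        charge=int(grp.attrs["charge"]),
        multiplicity=int(grp.attrs["multiplicity"]),
    )


def _write_sidecar(path: Path, meta: dict):
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# training-set builders

def reference_record(geom: Geometry, ref: Geometry, spec: MethodSpec):
    """Align, run the engine, return the per-sample record (internal frame).

    The geometry is aligned to ``ref`` *before* the engine call, so the
    potential/1-rdm pair, the forces and the dipole are all expressed in
    the internal frame directly.
    """
    aligned, _ = align_to_reference(geom, ref)
    res = run_reference(aligned, spec)
    ao = compute_ao_matrices(aligned, spec)
    return {
        "coords": aligned.coords,
        "v": ao.v,
        "gamma": res.gamma,
        "energy": res.energy,
        "forces": res.forces,
        "dipole": res.dipole,
    }


def build_training_set(conformers, spec: MethodSpec, plan: SamplePlan,
                       modes_list=None, progress=None, checkpoint=None,
                       max_records=None) -> TrainingSet:
    """Sample each conformer's normal modes and run the reference engine.

    ``conformers`` — relaxed equilibrium geometries (one per conformer).
    Samples whose SCF fails are logged and skipped.  Deterministic for a
    fixed plan seed (conformer k uses sub-seed seed+k); with
    ``checkpoint`` set, partial results are saved after every record and
    an interrupted build resumes to identical content.  ``max_records``
    stops the build early (used to exercise resumption).
    """
    if isinstance(conformers, Geometry):
        conformers = [conformers]
    records, ref_idx = [], []
    n_done = 0
    if checkpoint is not None and Path(checkpoint).exists():
        part = TrainingSet.load(checkpoint)
        if part.spec.to_dict() != spec.to_dict():
            raise ValueError("checkpoint method metadata does not match")
        for i in range(part.n_samples):
            records.append({
                "coords": part.coords[i], "v": part.potentials[i],
                "gamma": part.gammas[i], "energy": part.energies[i],
                "forces": part.forces[i], "dipole": part.dipoles[i],
            })
            ref_idx.append(int(part.ref_index[i]))
        n_done = int(part.plan.get("_n_seen", part.n_samples))
        log.info("resuming training-set build from %d records", n_done)
    seen = 0
    for k, eq in enumerate(conformers):
        modes = (modes_list[k] if modes_list is not None
                 else normal_mode_analysis(eq, spec))
        sub_plan = SamplePlan(
            temperature=plan.temperature,
            n_samples=plan.n_samples, seed=plan.seed + k,
        )
        for geom in generate_samples(modes, sub_plan):
            seen += 1
            if seen <= n_done:
                continue
            if max_records is not None and len(records) >= max_records:
                break
            try:
                rec = reference_record(geom, eq, spec)
            except EngineError as err:
                log.warning("skipping failed sample (%s): %s",
                            geom.comment, err)
                continue
            records.append(rec)
            ref_idx.append(k)
            if checkpoint is not None:
                _records_to_set(records, ref_idx, list(conformers), spec,
                                {**plan.to_dict(), "_n_seen": seen},
                                ).save(checkpoint)
            if progress is not None:
                progress(len(records))
    return _records_to_set(records, ref_idx, list(conformers), spec,
                           plan.to_dict())


def training_set_from_geometries(geoms, spec: MethodSpec,
                                 references=None) -> TrainingSet:
    """Build a set from explicit geometries (e.g. bond scans).

    Each geometry is aligned to the first supplied reference with
    matching atom symbols (or to itself when none matches, e.g. mixed
    isoelectronic species constructed directly in the internal frame).
    """
    if references is None:
        references = []
        for g in geoms:
            if not any(r.symbols == g.symbols for r in references):
                references.append(g)
    records, ref_idx = [], []
    for g in geoms:
        k = next((i for i, r in enumerate(references)
                  if r.symbols == g.symbols), None)
        if k is None:
            references.append(g)
            k = len(references) - 1
        try:
            rec = reference_record(g, references[k], spec)
        except EngineError as err:
            log.warning("skipping failed geometry: %s", err)
            continue
        records.append(rec)
        ref_idx.append(k)
    return _records_to_set(records, ref_idx, list(references), spec,
                           {"source": "explicit-geometries"})


def _records_to_set(records, ref_idx, references, spec, plan_dict):
    if not records:
        raise ValueError("no successful reference calculations")
    n_ao = records[0]["v"].shape[0]
    for r in records:
        if r["v"].shape[0] != n_ao:
            raise ValueError("samples do not share one AO dimension")
    return TrainingSet(
        spec=spec,
        references=references,
        ref_index=np.array(ref_idx, dtype=np.int64),
        coords=[r["coords"] for r in records],
        potentials=np.stack([r["v"] for r in records]),
        gammas=np.stack([r["gamma"] for r in records]),
        energies=np.array([r["energy"] for r in records]),
        forces=np.stack([r["forces"] for r in records]),
        dipoles=np.stack([r["dipole"] for r in records]),
        plan=plan_dict,
    )


# ---------------------------------------------------------------------------
# model persistence

def save_model(path, surrogate) -> None:
    """Persist a fitted DensitySurrogate (bit-exact matrices)."""
    path = Path(path)
    gm = surrogate.gamma_model_
    dm = surrogate.delta_model_
    with h5py.File(path, "w") as f:
        _write_meta(f, {
            "kind": "surrogate_model",
            "spec": surrogate.spec.to_dict(),
            "lam": surrogate.lam,
            "lambda_selected": float(getattr(gm, "lambda_", 0.0)),
            "alpha": surrogate.alpha,
            "purify": surrogate.purify,
            "version": _pkg_version,
            "delta_targets": list(dm.targets_),
            "target_shapes": {k: list(v) for k, v in dm.target_shapes_.items()},
        })
        rg = f.create_group("references")
        for i, ref in enumerate(surrogate.references_saved()):
            _write_geometry(rg.create_group(str(i)), ref)
        f["V_train"] = gm.V_train_
        f["beta"] = gm.beta_
        dg = f.create_group("delta")
        for name, ridge in dm.models_.items():
            g = dg.create_group(name)
            g["coef"] = ridge.coef_
            g["intercept"] = np.atleast_1d(ridge.intercept_)
    _write_sidecar(path, {
        "kind": "surrogate_model", "spec": surrogate.spec.to_dict(),
        "lam": surrogate.lam, "alpha": surrogate.alpha,
        "version": _pkg_version,
    })


def load_model(path):
    from sklearn.linear_model import Ridge

    from .models import DeltaRefiner, GammaKRR
    from .surrogate import DensitySurrogate

    with h5py.File(path, "r") as f:
        meta = _read_meta(f)
        refs = [_read_geometry(f["references"][k])
                for k in sorted(f["references"], key=int)]
        surr = DensitySurrogate(
            spec=MethodSpec.from_dict(meta["spec"]),
            lam=meta["lam"], alpha=meta["alpha"], purify=meta["purify"],
        )
        gm = GammaKRR(lam=meta["lam"])
        gm.V_train_ = f["V_train"][()]
        gm.beta_ = f["beta"][()]
        gm.n_ao_ = gm.V_train_.shape[1]
        gm.lambda_ = meta.get("lambda_selected", 0.0)
        gm.condition_number_ = np.nan
        dm = DeltaRefiner(alpha=meta["alpha"])
        dm.n_ao_ = gm.n_ao_
        dm.models_, dm.target_shapes_, dm.residuals_ = {}, {}, {}
        for name in meta["delta_targets"]:
            ridge = Ridge(alpha=meta["alpha"], fit_intercept=True)
            ridge.coef_ = f["delta"][name]["coef"][()]
            ridge.intercept_ = f["delta"][name]["intercept"][()]
            dm.models_[name] = ridge
            dm.target_shapes_[name] = tuple(meta["target_shapes"][name])
        surr.gamma_model_ = gm
        surr.delta_model_ = dm
        surr.reference_ = refs[0]
        surr.references_all_ = refs
        surr.n_electrons_ = refs[0].n_electrons
        return surr


# ---------------------------------------------------------------------------
# benchmark report (Table-2-style RMSD conventions)

def rmsd_report(surrogate, test_geometries, spec=None) -> dict:
    """RMSDs of surrogate predictions against the engine on test geometries.

    Conventions: energy and non-interacting kinetic energy in kcal/mol;
    forces as the RMSD of per-atom force-magnitude errors in
    kcal·mol⁻¹·Å⁻¹; dipole as the RMSD of |μ| errors per vibrational
    degree of freedom in 10⁻³ D.
    """
    from . import engine as qm
    from .rdm import dipole_moment, kinetic_energy, purify_aufbau
    from .sampler import n_vibrational
    from .units import ANG_TO_BOHR, HARTREE_TO_KCALMOL

    spec = spec or surrogate.spec
    n_vib = n_vibrational(test_geometries[0])
    variants = ("gamma_p", "gamma_p+delta", "direct")
    E = {v: [] for v in variants}
    Fmag = {v: [] for v in variants}
    mu = {v: [] for v in variants}
    Ts = {v: [] for v in variants}
    ref = {"E": [], "F": [], "mu": [], "T": []}

    for g_raw in test_geometries:
        # work in the aligned frame throughout: scalar observables and
        # force magnitudes are rotation invariant, and the engine then
        # shares its per-geometry integral cache with the surrogate
        g, _ = surrogate._aligned(g_raw)
        res = run_reference(g, spec)
        ao = compute_ao_matrices(g, spec)
        ref["E"].append(res.energy)
        ref["F"].append(np.linalg.norm(res.forces, axis=1))
        ref["mu"].append(np.linalg.norm(res.dipole))
        ref["T"].append(kinetic_energy(res.gamma, ao.t))

        gp_raw = surrogate.gamma_model_.predict_one(ao.v)
        gref_raw = gp_raw + surrogate.delta_model_.predict_one(
            gp_raw, "delta_gamma")
        gref_raw = 0.5 * (gref_raw + gref_raw.T)
        do_purify = surrogate.purify and spec.theory != "FullCI"
        for variant, gam in (("gamma_p", gp_raw), ("gamma_p+delta", gref_raw)):
            if do_purify:
                gam = purify_aufbau(gam, ao.S, g.n_electrons)
            E[variant].append(qm.energy_from_rdm(gam, g, spec))
            f = qm.forces_from_rdm(gam, g, spec)
            Fmag[variant].append(np.linalg.norm(f, axis=1))
            mu[variant].append(np.linalg.norm(dipole_moment(gam, ao.D, g)))
            Ts[variant].append(kinetic_energy(gam, ao.t))
        # direct: energy/forces from map 2 itself; expectation values are
        # always computed from the refined 1-rdm
        E["direct"].append(
            float(surrogate.delta_model_.predict_one(gp_raw, "energy")[0]))
        f_dir = surrogate.delta_model_.predict_one(gp_raw, "forces")
        Fmag["direct"].append(np.linalg.norm(f_dir, axis=1))
        mu["direct"].append(mu["gamma_p+delta"][-1])
        Ts["direct"].append(Ts["gamma_p+delta"][-1])

    f_au_to_kcal = HARTREE_TO_KCALMOL * ANG_TO_BOHR
    rows = {}
    for v in variants:
        rows[v] = {
            "energy_rmsd_kcal": float(
                _rmsd(np.array(E[v]) - np.array(ref["E"])) * HARTREE_TO_KCALMOL),
            "force_rmsd_kcal_per_A": float(
                _rmsd((np.array(Fmag[v]) - np.array(ref["F"])).ravel())
                * f_au_to_kcal),
            "dipole_rmsd_mD_per_nvib": float(
                _rmsd(np.array(mu[v]) - np.array(ref["mu"])) * 1e3 / n_vib),
            "kinetic_rmsd_kcal": float(
                _rmsd(np.array(Ts[v]) - np.array(ref["T"])) * HARTREE_TO_KCALMOL),
        }
    return rows


def _rmsd(x):
    x = np.asarray(x, dtype=float)
    return np.sqrt(np.mean(x * x))
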