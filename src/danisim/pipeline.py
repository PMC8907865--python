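"""Staged pipeline with hash-based idempotence.

Stage order: phantom -> prep -> fit_regressors -> train -> train_sr ->
simulate -> evaluate.  Every stage directory records the config hash and
the content checksums of its key artifacts in ``stage.json``; a rerun with
an unchanged configuration and intact upstream artifacts is skipped, and a
downstream stage refuses to run when an upstream artifact no longer
matches its recorded checksum.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import evaluation, phantom as phantom_mod, regional, sr as sr_mod
from .config import RunConfig
from .prep import (AgeBinning, NormRecord, SliceStack, build_age_bins,
                   build_region_set, central_slice_indices, normalize_slices)
from .simulate import interpolate_age, personalize, simulate_sequence
from .train import ProgressionModel, SliceDataset, train_all

__all__ = ["STAGES", "DependencyError", "run_pipeline"]

STAGES = ["phantom", "prep", "fit_regressors", "train", "train_sr",
          "simulate", "evaluate"]

_UPSTREAM = {
    "phantom": [],
    "prep": ["phantom"],
    "fit_regressors": ["prep"],
    "train": ["prep", "fit_regressors"],
    "train_sr": ["train"],
    "simulate": ["train", "train_sr"],
    "evaluate": ["phantom", "simulate"],
}

# artifact files whose content integrity downstream stages depend on
_KEY_ARTIFACTS = {
    "phantom": ["manifest.csv", "atlas.nii.gz"],
    "prep": ["meta.json", "stacks.npz"],
    "fit_regressors": ["lr_bank.json"],
    "train": ["model/meta.json"],
    "train_sr": ["sr.npz"],
    "simulate": ["result.json"],
    "evaluate": ["report.csv"],
}


class DependencyError(RuntimeError):
    pass


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_dir(workdir: Path, stage: str) -> Path:
    return workdir / stage


def _upstream_digests(workdir: Path, stage: str) -> dict[str, dict[str, str]]:
    out = {}
    for up in _UPSTREAM[stage]:
        stamp_path = _stage_dir(workdir, up) / "stage.json"
        if stamp_path.exists():
            out[up] = json.loads(stamp_path.read_text()).get("artifacts", {})
    return out


def _write_stamp(workdir: Path, stage: str, cfg: RunConfig) -> None:
    sdir = _stage_dir(workdir, stage)
    stamp = {
        "config_hash": cfg.hash,
        "artifacts": {rel: _sha(sdir / rel) for rel in _KEY_ARTIFACTS[stage]},
        "upstream": _upstream_digests(workdir, stage),
    }
    (sdir / "stage.json").write_text(json.dumps(stamp))


def _stamp_ok(workdir: Path, stage: str, cfg: RunConfig) -> bool:
    stamp_path = _stage_dir(workdir, stage) / "stage.json"
    if not stamp_path.exists():
        return False
    stamp = json.loads(stamp_path.read_text())
    if stamp.get("config_hash") != cfg.hash:
        return False
    for rel, digest in stamp.get("artifacts", {}).items():
        f = _stage_dir(workdir, stage) / rel
        if not f.exists() or _sha(f) != digest:
            return False
    # a stage is stale when any upstream artifact changed since it ran
    if stamp.get("upstream", {}) != _upstream_digests(workdir, stage):
        return False
    for up, artifacts in stamp.get("upstream", {}).items():
        for rel, digest in artifacts.items():
            f = _stage_dir(workdir, up) / rel
            if not f.exists() or _sha(f) != digest:
                return False
    return True


def _require_upstream(workdir: Path, stage: str, cfg: RunConfig) -> None:
    for up in _UPSTREAM[stage]:
        stamp_path = _stage_dir(workdir, up) / "stage.json"
        if not stamp_path.exists():
            raise DependencyError(f"stage {stage!r} needs {up!r} to run first")
        stamp = json.loads(stamp_path.read_text())
        for rel, digest in stamp.get("artifacts", {}).items():
            f = _stage_dir(workdir, up) / rel
            if not f.exists() or _sha(f) != digest:
                raise DependencyError(
                    f"artifact {up}/{rel} is missing or was modified "
                    "after its stage ran")


# --------------------------------------------------------------------------
# stage bodies
# --------------------------------------------------------------------------

def _stage_phantom(cfg: RunConfig, workdir: Path) -> None:
    out = _stage_dir(workdir, "phantom")
    out.mkdir(parents=True, exist_ok=True)
    cohort = phantom_mod.generate_cohort(cfg.cohort_spec())
    phantom_mod.write_cohort(cohort, out)


def _stage_prep(cfg: RunConfig, workdir: Path) -> None:
    out = _stage_dir(workdir, "prep")
    out.mkdir(parents=True, exist_ok=True)
    cohort = phantom_mod.read_cohort(_stage_dir(workdir, "phantom") / "manifest.csv")
    t = cfg["prep"]["T"]
    depth = cohort.subjects[0].scans[0][1].shape[2]
    if t > depth:
        raise DependencyError(f"prep.T={t} exceeds volume depth {depth}")
    arrays: dict[str, np.ndarray] = {}
    rows = []
    records: dict[str, list[list[float]]] = {}
    ages_all = []
    for sub in cohort.subjects:
        for vi, (age, vol) in enumerate(sub.scans):
            stack = normalize_slices(vol, t, subject_id=sub.subject_id, age=age)
            key = f"{sub.subject_id}|{vi}"
            arrays[key] = stack.slices
            records[key] = [[r.mean, r.sd, r.zmin, r.zmax]
                            for r in stack.norm_records]
            rows.append({"key": key, "subject_id": sub.subject_id, "visit": vi,
                         "age": age, "dx": sub.diagnosis})
            ages_all.append(age)
    binning = build_age_bins(ages_all, cfg["prep"]["A"], cfg["prep"]["c"])
    slice_indices = central_slice_indices(depth, t)
    meta = {
        "rows": rows,
        "slice_indices": slice_indices.tolist(),
        "binning": {"edges": binning.edges.tolist(),
                    "centers": binning.centers.tolist(),
                    "deltas": binning.deltas.tolist(),
                    "sigmas": binning.sigmas.tolist(), "c": binning.c},
        "norm_records": records,
    }
    np.savez(out / "stacks.npz", **arrays)
    (out / "meta.json").write_text(json.dumps(meta))


def _load_prep(workdir: Path):
    pdir = _stage_dir(workdir, "prep")
    meta = json.loads((pdir / "meta.json").read_text())
    b = meta["binning"]
    binning = AgeBinning(np.asarray(b["edges"]), np.asarray(b["centers"]),
                         np.asarray(b["deltas"]), np.asarray(b["sigmas"]), b["c"])
    slice_indices = np.asarray(meta["slice_indices"])
    stacks = {}
    with np.load(pdir / "stacks.npz") as zf:
        for row in meta["rows"]:
            key = row["key"]
            recs = [NormRecord(*vals) for vals in meta["norm_records"][key]]
            stacks[key] = (row, SliceStack(row["subject_id"], row["age"],
                                           zf[key], recs, slice_indices))
    return binning, slice_indices, stacks


def _region_sets(cfg: RunConfig, workdir: Path, slice_indices) -> dict:
    atlas = np.asarray(nib.load(
        _stage_dir(workdir, "phantom") / "atlas.nii.gz").dataobj).astype(int)
    radii = tuple(cfg["prep"]["radii"])
    return {int(n): build_region_set(atlas[:, :, int(n)], int(n), radii)
            for n in slice_indices}


def _stage_fit_regressors(cfg: RunConfig, workdir: Path) -> None:
    out = _stage_dir(workdir, "fit_regressors")
    out.mkdir(parents=True, exist_ok=True)
    _, slice_indices, stacks = _load_prep(workdir)
    rsets = _region_sets(cfg, workdir, slice_indices)
    by_subject: dict[str, list] = {}
    for row, stack in stacks.values():
        by_subject.setdefault(row["subject_id"], []).append(
            (row["age"], row["dx"], stack))
    bank = regional.fit_bank(by_subject, [rsets[n] for n in sorted(rsets)])
    bank.save(out / "lr_bank.json")


def _stage_train(cfg: RunConfig, workdir: Path) -> None:
    out = _stage_dir(workdir, "train")
    out.mkdir(parents=True, exist_ok=True)
    binning, slice_indices, stacks = _load_prep(workdir)
    rsets = _region_sets(cfg, workdir, slice_indices)
    bank = regional.RegressorBank.load(
        _stage_dir(workdir, "fit_regressors") / "lr_bank.json")
    slice_data = {}
    for pos, n in enumerate(slice_indices):
        x = np.stack([stack.slices[pos] for _, stack in stacks.values()])
        ages = np.array([row["age"] for row, _ in stacks.values()])
        dx = np.array([row["dx"] for row, _ in stacks.values()])
        slice_data[int(n)] = SliceDataset(x=x, ages=ages, dx=dx)
    model = train_all(slice_data, rsets, bank, binning, cfg.model_config(),
                      cfg.train_config(), cfg.pwf_params())
    model.save(out / "model")


def _stage_train_sr(cfg: RunConfig, workdir: Path) -> None:
    out = _stage_dir(workdir, "train_sr")
    out.mkdir(parents=True, exist_ok=True)
    model = ProgressionModel.load(_stage_dir(workdir, "train") / "model")
    _, _, stacks = _load_prep(workdir)
    entries = [(stack, row["dx"]) for row, stack in stacks.values()]
    entries = entries[: cfg["sr"]["max_pairs"]]
    pairs = sr_mod.make_pairs(model, entries)
    net, log = sr_mod.train_sr(pairs, cfg.sr_config())
    sr_mod.save_sr(net, out / "sr.npz")
    log.to_csv(out / "losses.csv", index=False)


def _choose_subject(cfg: RunConfig, cohort) -> "phantom_mod.SubjectRecord":
    wanted = cfg["simulate"]["subject_id"]
    if wanted is not None:
        for sub in cohort.subjects:
            if sub.subject_id == wanted:
                return sub
        raise DependencyError(f"subject {wanted!r} not in cohort")
    for sub in cohort.subjects:
        if len(sub.scans) >= 2:
            return sub
    raise DependencyError("no subject with a follow-up scan to simulate")


def _stage_simulate(cfg: RunConfig, workdir: Path) -> None:
    out = _stage_dir(workdir, "simulate")
    out.mkdir(parents=True, exist_ok=True)
    model = ProgressionModel.load(_stage_dir(workdir, "train") / "model")
    net = sr_mod.load_sr(_stage_dir(workdir, "train_sr") / "sr.npz")
    cohort = phantom_mod.read_cohort(_stage_dir(workdir, "phantom") / "manifest.csv")
    sub = _choose_subject(cfg, cohort)
    baseline_age, baseline = sub.scans[0]
    followup_age, _ = sub.scans[-1]
    tuned = personalize(model, baseline, baseline_age, sub.diagnosis,
                        iters=cfg["simulate"]["personalize_iters"])
    result = simulate_sequence(tuned, baseline, baseline_age, sub.diagnosis,
                               subject_id=sub.subject_id, sr_net=net)
    affine = np.eye(4)
    for i, vol in enumerate(result.volumes):
        nib.save(nib.Nifti1Image(vol, affine), out / f"sim_bin{i:02d}.nii.gz")
    target = float(np.clip(followup_age, result.bin_ages[0], result.bin_ages[-1]))
    at_followup = interpolate_age(result, target)
    nib.save(nib.Nifti1Image(at_followup, affine), out / "sim_at_followup.nii.gz")
    (out / "result.json").write_text(json.dumps({
        "subject_id": sub.subject_id, "baseline_age": baseline_age,
        "followup_age": followup_age, "interpolated_age": target,
        "diagnosis": sub.diagnosis, "bin_ages": result.bin_ages.tolist(),
        "config_hash": cfg.hash,
    }))


def _stage_evaluate(cfg: RunConfig, workdir: Path) -> None:
    out = _stage_dir(workdir, "evaluate")
    out.mkdir(parents=True, exist_ok=True)
    sim_dir = _stage_dir(workdir, "simulate")
    info = json.loads((sim_dir / "result.json").read_text())
    cohort = phantom_mod.read_cohort(_stage_dir(workdir, "phantom") / "manifest.csv")
    sub = next(s for s in cohort.subjects if s.subject_id == info["subject_id"])
    real = sub.scans[-1][1]
    sim = np.asarray(nib.load(sim_dir / "sim_at_followup.nii.gz").dataobj)
    atlas = cohort.atlas
    brain = atlas > 0
    threshold = cfg["evaluate"]["threshold"]
    rows = []
    for q in range(1, int(atlas.max()) + 1):
        err = evaluation.volumetric_error(sim, real, atlas == q, brain, threshold)
        rows.append({"subject": sub.subject_id, "region": f"region_{q}",
                     "err": err})
    report = evaluation.cohort_report(pd.DataFrame(rows))
    report.summary.to_csv(out / "report.csv")
    report.per_subject.to_csv(out / "errors.csv", index=False)


_BODIES = {
    "phantom": _stage_phantom,
    "prep": _stage_prep,
    "fit_regressors": _stage_fit_regressors,
    "train": _stage_train,
    "train_sr": _stage_train_sr,
    "simulate": _stage_simulate,
    "evaluate": _stage_evaluate,
}


def run_pipeline(stages: list[str], cfg: RunConfig,
                 workdir: str | Path) -> dict[str, str]:
    """Run the requested stages in dependency order; skip up-to-date ones.

    Returns a mapping stage -> "ran" | "skipped".
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    status = {}
    for stage in ordered:
        if _stamp_ok(workdir, stage, cfg):
            status[stage] = "skipped"
            continue
        _require_upstream(workdir, stage, cfg)
        _BODIES[stage](cfg, workdir)
        _write_stamp(workdir, stage, cfg)
        status[stage] = "ran"
    return status
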