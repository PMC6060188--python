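"""Cohort-table parsing, image I/O, configuration, and pipeline orchestration.

The cohort table is a TSV mirroring a clinical demographics table: one row per
lesion with patient id, sex, age, histopathology, WHO grade, verification
route (SB = stereotactic biopsy, EB = excisional biopsy/partial resection),
days between verification and PET, and the Ki-67 labelling index (numeric,
"<1", or "N/A").  The packaged reference cohort
(``flucipet/data/cohort_table1.tsv``) holds the 18-lesion / 16-patient study
table and drives cohort-level tests.

``run_pipeline`` wires the whole analysis end to end on a synthetic cohort:
simulate phantoms -> segment and measure -> TAC/equilibrium analysis ->
ROC/correlation/relevance statistics -> CSV/JSON reports.  Everything is
reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom as ph
from . import roi_metrics as rm
from . import tac_kinetics as tk
from . import discrimination_stats as ds

__all__ = [
    "LesionRecord",
    "CohortSummary",
    "read_cohort",
    "write_cohort",
    "packaged_cohort_path",
    "summarize_cohort",
    "save_dynamic_image",
    "load_dynamic_image",
    "save_mask",
    "load_mask",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

HISTOLOGIES = (
    "oligodendroglioma",
    "diffuse astrocytoma",
    "anaplastic astrocytoma",
    "glioblastoma",
)
WHO_GRADES = ("II", "III", "IV")
VERIFICATIONS = ("SB", "EB")

COHORT_COLUMNS = [
    "lesion_id", "patient_id", "sex", "age", "histology",
    "who_grade", "verification", "days_before_pet", "ki67_percent",
]


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionRecord:
    """One cohort-table row.  ``ki67_percent`` keeps the raw token ("<1",
    "N/A", or a number as text); ``ki67_value`` is the numeric accessor."""

    lesion_id: str
    patient_id: str
    sex: str
    age: int
    histology: str
    who_grade: str
    verification: str
    days_before_pet: int
    ki67_percent: str

    @property
    def grade_class(self) -> str:
        return ds.grade_class(self.who_grade)

    def ki67_value(self, less_than_one: float = 0.5) -> float | None:
        """Numeric Ki-67: '<1' maps to ``less_than_one`` (interval midpoint),
        'N/A' to None."""
        v = ds.parse_ki67(self.ki67_percent)
        if v == 0.5 and self.ki67_percent.strip().startswith("<"):
            return less_than_one
        return v


def packaged_cohort_path() -> Path:
    """Path of the packaged 18-lesion reference cohort TSV."""
    return Path(str(resources.files("flucipet").joinpath("data/cohort_table1.tsv")))


def read_cohort(path) -> list[LesionRecord]:
    """Parse a cohort TSV into typed records.

    Unknown histology / grade / verification values raise naming the row;
    an empty file returns an empty list with a warning.
    """
    import warnings

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if df.empty:
        warnings.warn(f"cohort table {path} has no rows")
        return []
    records = []
    for i, row in df.iterrows():
        hist = row["histology"].strip().lower()
        if hist not in HISTOLOGIES:
            raise ValueError(f"row {i + 1} (lesion {row['lesion_id']}): unknown histology {row['histology']!r}")
        grade = row["who_grade"].strip().upper()
        if grade not in WHO_GRADES:
            raise ValueError(f"row {i + 1} (lesion {row['lesion_id']}): unknown WHO grade {row['who_grade']!r}")
        ver = row["verification"].strip().upper()
        if ver not in VERIFICATIONS:
            raise ValueError(f"row {i + 1} (lesion {row['lesion_id']}): unknown verification {row['verification']!r}")
        days = int(row["days_before_pet"])
        if days < 0:
            raise ValueError(f"row {i + 1}: days_before_pet must be >= 0")
        records.append(
            LesionRecord(
                lesion_id=row["lesion_id"].strip(),
                patient_id=row["patient_id"].strip(),
                sex=row["sex"].strip().upper(),
                age=int(row["age"]),
                histology=hist,
                who_grade=grade,
                verification=ver,
                days_before_pet=days,
                ki67_percent=row["ki67_percent"].strip(),
            )
        )
    return records


def write_cohort(records: list[LesionRecord], path) -> None:
    """Write records back to TSV; round-trips through :func:`read_cohort`."""
    pd.DataFrame([asdict(r) for r in records])[COHORT_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class CohortSummary:
    n_lesions: int
    n_patients: int
    histology_counts: dict[str, int]
    grade_class_counts: dict[str, int]
    who_grade_counts: dict[str, int]
    mean_days_before_pet: float  # per patient, one value each
    mean_age: float  # per patient; reported, see docs/methods.md
    ki67_evaluable: int
    ki67_missing: int


def summarize_cohort(records: list[LesionRecord]) -> CohortSummary:
    """Cohort counts; patient-level means use one row per distinct patient."""
    if not records:
        raise ValueError("no records to summarize")
    per_patient: dict[str, LesionRecord] = {}
    for r in records:
        per_patient.setdefault(r.patient_id, r)
    hist = {h: sum(r.histology == h for r in records) for h in HISTOLOGIES}
    grades = {g: sum(r.who_grade == g for r in records) for g in WHO_GRADES}
    cls = {c: sum(r.grade_class == c for r in records) for c in ("LGG", "HGG")}
    evaluable = sum(r.ki67_value() is not None for r in records)
    return CohortSummary(
        n_lesions=len(records),
        n_patients=len(per_patient),
        histology_counts=hist,
        grade_class_counts=cls,
        who_grade_counts=grades,
        mean_days_before_pet=float(
            np.mean([r.days_before_pet for r in per_patient.values()])
        ),
        mean_age=float(np.mean([r.age for r in per_patient.values()])),
        ki67_evaluable=evaluable,
        ki67_missing=len(records) - evaluable,
    )


# ---------------------------------------------------------------------------
# NIfTI + sidecar I/O
# ---------------------------------------------------------------------------

def save_dynamic_image(img: ph.DynamicImage, path) -> None:
    """Write a 4D NIfTI plus a JSON frame-timing sidecar.

    The sidecar carries ``FrameTimesStart`` and ``FrameDuration`` in seconds,
    next to the image as ``<stem>.json``.
    """
    import nibabel as nib

    path = Path(path)
    affine = np.diag([img.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = img.origin_mm
    nib.save(nib.Nifti1Image(img.voxels.astype(np.float64), affine), path)
    sidecar = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "FrameTimesStart": img.schedule.frame_starts.tolist(),
                "FrameDuration": img.schedule.frame_durations.tolist(),
            },
            indent=1,
        )
    )


def load_dynamic_image(path) -> ph.DynamicImage:
    """Read a 4D NIfTI and its frame-timing sidecar back into a DynamicImage."""
    import nibabel as nib

    path = Path(path)
    nii = nib.load(path)
    vox = np.asarray(nii.dataobj, dtype=float)
    zooms = nii.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], atol=1e-6):
        raise ValueError("anisotropic voxels are not supported")
    sidecar = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
    timing = json.loads(sidecar.read_text())
    schedule = ph.FrameSchedule(
        np.asarray(timing["FrameTimesStart"], float),
        np.asarray(timing["FrameDuration"], float),
    )
    origin = tuple(float(x) for x in nii.affine[:3, 3])
    return ph.DynamicImage(vox, float(zooms[0]), schedule, origin)


def save_mask(mask: rm.VoxelMask, path, origin_mm=(0.0, 0.0, 0.0)) -> None:
    import nibabel as nib

    affine = np.diag([mask.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = origin_mm
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), Path(path))


def load_mask(path) -> rm.VoxelMask:
    import nibabel as nib

    nii = nib.load(Path(path))
    return rm.VoxelMask(np.asarray(nii.dataobj) > 0, float(nii.header.get_zooms()[0]))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run parameters; everything else derives from these + seed.

    The default geometry is one small head phantom per lesion: a 120 x 120 x
    102 mm grid at 3-mm voxels, brain ellipsoid semi-axes (52, 56, 44) mm, one
    9-mm-radius lesion in the left hemisphere, a venous-confluence sphere, and
    the contralateral 15-mm background sphere obtained by mirroring the lesion
    center across the midsagittal plane.
    """

    n_hgg: int = 12
    n_lgg: int = 6
    seed: int = 0
    grid_shape: tuple[int, int, int] = (40, 40, 34)
    voxel_size_mm: float = 3.0
    psf_fwhm_mm: float = ph.DEFAULT_PSF_FWHM_MM
    noise_sigma: float = 0.05
    lesion_radius_mm: float = 9.0
    search_diameter_mm: float = 30.0
    thresholds: tuple[float, ...] = rm.DEFAULT_THRESHOLDS
    window_start_min: float = tk.EQUILIBRIUM_WINDOW_START_MIN
    alpha: float = 0.05
    correlation_time_min: float = 30.0

    def validate(self) -> None:
        if self.n_hgg + self.n_lgg < 1:
            raise ValueError("config defines no lesions")
        if self.n_hgg < 1 or self.n_lgg < 1:
            raise ValueError("need at least one lesion of each grade class")


def _lesion_phantom_spec(cfg: PipelineConfig, lesion: ph.SyntheticLesion, seed: int) -> ph.PhantomSpec:
    center = tuple(cfg.voxel_size_mm * (np.array(cfg.grid_shape) - 1) / 2.0)
    lesion_center = (center[0] + 25.0, center[1] + 8.0, center[2] + 4.0)
    venous_center = (center[0], center[1] - 40.0, center[2] - 10.0)
    return ph.PhantomSpec(
        grid_shape=cfg.grid_shape,
        voxel_size_mm=cfg.voxel_size_mm,
        brain_center_mm=center,
        brain_semiaxes_mm=(52.0, 56.0, 44.0),
        lesions=(
            ph.LesionSpec(
                lesion_id=lesion.lesion_id,
                center_mm=lesion_center,
                radius_mm=cfg.lesion_radius_mm,
                kinetics=lesion.kinetics,
                grade_label=lesion.grade_class,
            ),
        ),
        normal_brain_kinetics=ph.normal_brain_kinetics(),
        venous_center_mm=venous_center,
        venous_radius_mm=6.0,
        venous_kinetics=ph.venous_kinetics(),
        psf_fwhm_mm=cfg.psf_fwhm_mm,
        noise_sigma=cfg.noise_sigma,
        seed=seed,
    )


def measure_lesion(
    cfg: PipelineConfig, lesion: ph.SyntheticLesion, seed: int
) -> pd.DataFrame:
    """Simulate one lesion's scan and measure it; returns the per-frame rows.

    Adds normal-brain and venous SUV_mean columns (for TAC/ANOVA groups) and
    applies attrition: a non-completing patient's 60-min frame rows are
    dropped (represented downstream as missing).
    """
    spec = _lesion_phantom_spec(cfg, lesion, seed)
    img, _truth = ph.render_phantom(spec)
    les = spec.lesions[0]
    midplane_x = spec.brain_center_mm[0]
    search = rm.sphere_mask(
        rm.SphereROI(les.center_mm, cfg.search_diameter_mm),
        cfg.grid_shape, cfg.voxel_size_mm,
    )
    bg_roi = rm.SphereROI(
        rm.mirror_contralateral(les.center_mm, midplane_x),
        rm.BACKGROUND_SPHERE_DIAMETER_MM,
    )
    bg_mask = rm.sphere_mask(bg_roi, cfg.grid_shape, cfg.voxel_size_mm)
    ven_mask = rm.sphere_mask(
        rm.SphereROI(spec.venous_center_mm, 2 * spec.venous_radius_mm),
        cfg.grid_shape, cfg.voxel_size_mm,
    )
    df = rm.metrics_table(img, {lesion.lesion_id: search}, bg_mask, cfg.thresholds)
    ven = img.voxels[ven_mask.mask, :].mean(axis=0)
    df["venous_mean"] = ven[df["frame_index"].to_numpy()]
    df["grade_class"] = lesion.grade_class
    df["who_grade"] = lesion.who_grade
    if not lesion.completed_full:
        last = img.schedule.n_frames - 1
        df = df[df["frame_index"] != last]
    return df


def run_pipeline(cfg: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Simulate -> segment -> TAC -> discriminate -> correlate; write reports.

    Writes to ``out_dir``: ``cohort.tsv``, ``metrics.csv``, ``tac_report.json``,
    ``roc_table.csv``, ``correlation.json``, ``relevance.json``, and
    ``summary.txt``.  Returns the collected results as a dict.  Fully
    deterministic given (cfg, seed).
    """
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    cohort_seed, *scan_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(1 + cfg.n_hgg + cfg.n_lgg)
    ]

    logger.info("stage=simulate n_hgg=%d n_lgg=%d seed=%d", cfg.n_hgg, cfg.n_lgg, seed)
    lesions = ph.synthesize_cohort(cfg.n_hgg, cfg.n_lgg, seed=cohort_seed)
    records = [
        LesionRecord(
            lesion_id=l.lesion_id,
            patient_id=f"SP{i + 1:02d}",  # synthetic: one patient per lesion
            sex="F" if i % 2 else "M",
            age=50,
            histology="glioblastoma" if l.grade_class == "HGG" else "oligodendroglioma",
            who_grade=l.who_grade,
            verification="SB",
            days_before_pet=14,
            ki67_percent="N/A" if l.ki67_percent is None else f"{l.ki67_percent:.1f}",
        )
        for i, l in enumerate(lesions)
    ]
    write_cohort(records, out / "cohort.tsv")

    logger.info("stage=segment thresholds=%s", cfg.thresholds)
    frames = [measure_lesion(cfg, l, s) for l, s in zip(lesions, scan_seeds)]
    metrics = pd.concat(frames, ignore_index=True)
    metrics.to_csv(out / "metrics.csv", index=False)
    logger.info("stage=segment rows=%d", len(metrics))

    # --- TAC / equilibrium: lesion SUV_max vs normal and venous SUV_mean ----
    obs_rows = []
    for _, r in metrics.iterrows():
        obs_rows.append((r["lesion_id"], r["grade_class"], r["time_min"], r["suv_max"]))
        obs_rows.append((f"{r['lesion_id']}-brain", "normal", r["time_min"], r["background_mean"]))
        obs_rows.append((f"{r['lesion_id']}-venous", "venous", r["time_min"], r["venous_mean"]))
    obs = pd.DataFrame(obs_rows, columns=["lesion", "group", "time_point", "value"])
    eq = tk.equilibrium_anova(obs, cfg.window_start_min, cfg.alpha)
    tac_report = {
        "window_min": list(eq.window_min),
        "alpha": eq.alpha,
        "anova": {
            str(idx): {"F": _j(row["F"]), "p": _j(row["PR(>F)"])}
            for idx, row in eq.anova_table.iterrows()
        },
        "plateau": {g: eq.plateau[g] for g in eq.plateau},
        "tukey": {
            g: (None if t is None else t.to_dict(orient="records"))
            for g, t in eq.tukey_pairs.items()
        },
    }
    (out / "tac_report.json").write_text(json.dumps(tac_report, indent=1))
    logger.info("stage=tac groups=%s", sorted(eq.plateau))

    # --- ROC over pooled equilibrium observations ---------------------------
    grades = {l.lesion_id: l.grade_class for l in lesions}
    metric_cols = ["suv_max"] + [f"tb_mean_{k:g}" for k in cfg.thresholds]
    pooled = ds.pool_equilibrium(metrics, grades, tuple(metric_cols), cfg.window_start_min)
    roc_rows = []
    roc_results: dict[str, ds.ROCResult] = {}
    for m in metric_cols:
        try:
            r = ds.roc_from_observations(pooled, m)
        except ValueError as exc:
            # e.g. no low-grade lesion cleared a high threshold: that metric
            # has one class only and its ROC is not evaluable for this cohort
            logger.info("stage=discriminate metric=%s not evaluable (%s)", m, exc)
            roc_rows.append({"parameter": m, "threshold": np.nan,
                             "sensitivity_pct": np.nan, "specificity_pct": np.nan,
                             "auc": np.nan})
            continue
        roc_results[m] = r
        roc_rows.append(
            {
                "parameter": m,
                "threshold": round(r.optimal_threshold, 4),
                "sensitivity_pct": round(100 * r.sens_at_opt, 1),
                "specificity_pct": round(100 * r.spec_at_opt, 1),
                "auc": round(r.auc, 4),
            }
        )
    roc_table = pd.DataFrame(roc_rows)
    roc_table.to_csv(out / "roc_table.csv", index=False)
    logger.info("stage=discriminate observations=%d", len(pooled))

    # --- Welch t: WHO II vs WHO IV (grade III excluded) ---------------------
    tb_col = f"tb_mean_{cfg.thresholds[0]:g}"
    welch = {}
    win = metrics[metrics["time_min"] >= cfg.window_start_min - 1e-9]
    for t in sorted(win["time_min"].unique()):
        sub = win[win["time_min"] == t]
        a = sub[sub["who_grade"] == "IV"][tb_col].dropna()
        b = sub[sub["who_grade"] == "II"][tb_col].dropna()
        if len(a) >= 2 and len(b) >= 2:
            tstat, p = ds.welch_t(a, b)
            welch[f"{t:g}"] = {"t": _j(tstat), "p": _j(p)}

    # --- Ki-67 correlation at the correlation time point --------------------
    at_t = metrics[np.isclose(metrics["time_min"], cfg.correlation_time_min)]
    ki67 = {l.lesion_id: l.ki67_percent for l in lesions}
    corr = {}
    for m in ("suv_max", tb_col):
        sub = at_t.dropna(subset=[m])
        x = sub[m].to_numpy()
        y = np.array([np.nan if ki67[l] is None else ki67[l] for l in sub["lesion_id"]])
        try:
            c = ds.ki67_correlation(x, y)
        except ValueError as exc:
            logger.info("stage=correlate metric=%s not evaluable (%s)", m, exc)
            corr[m] = {"r": None, "p": None, "n": 0, "slope": None,
                       "intercept": None, "degenerate": True}
            continue
        corr[m] = {"r": _j(c.r), "p": _j(c.p), "n": c.n, "slope": _j(c.slope),
                   "intercept": _j(c.intercept), "degenerate": c.degenerate}
    (out / "correlation.json").write_text(
        json.dumps({"time_min": cfg.correlation_time_min, "welch_who2_vs_who4": welch,
                    "ki67": corr}, indent=1)
    )

    # --- Lasso relevance over the four uptake metrics -----------------------
    k0 = f"{cfg.thresholds[0]:g}"
    Xcols = {"suv_max": "suv_max", "suv_mean": f"suv_mean_{k0}",
             "tb_max": "tb_max", "tb_mean": f"tb_mean_{k0}"}
    lasso_df = win.dropna(subset=list(Xcols.values()))
    X = lasso_df[list(Xcols.values())].rename(columns={v: k for k, v in Xcols.items()})
    rel = ds.lasso_relevance(X, lasso_df["grade_class"].to_numpy(), seed=seed)
    (out / "relevance.json").write_text(
        json.dumps({"entry_order": rel.entry_order, "coefficients": rel.coefficients,
                    "relevant": rel.relevant, "chosen_C": rel.chosen_C}, indent=1)
    )

    summary = _summary_text(cfg, seed, len(metrics), eq, roc_table, welch, corr, rel)
    (out / "summary.txt").write_text(summary)
    return {
        "cohort": records,
        "metrics": metrics,
        "equilibrium": eq,
        "roc_table": roc_table,
        "roc_results": roc_results,
        "welch": welch,
        "correlation": corr,
        "relevance": rel,
    }


def _j(x):
    """JSON-safe float (NaN/inf -> None)."""
    x = float(x)
    return None if (np.isnan(x) or np.isinf(x)) else x


def _summary_text(cfg, seed, n_rows, eq, roc_table, welch, corr, rel) -> str:
    lines = [
        "flucipet pipeline summary",
        f"seed={seed}  lesions: {cfg.n_hgg} HGG + {cfg.n_lgg} LGG  metric rows: {n_rows}",
        f"equilibrium window starts at {cfg.window_start_min:g} min; alpha={cfg.alpha:g}",
        "",
        "Plateau (no significant within-group Tukey pair):",
    ]
    for g, p in sorted(eq.plateau.items()):
        lines.append(f"  {g}: {'n/a' if p is None else p}")
    lines += ["", "ROC (HGG positive, pooled equilibrium observations):",
              roc_table.to_string(index=False), "",
              "Ki-67 correlation at "
              f"{cfg.correlation_time_min:g} min:"]
    for m, c in corr.items():
        if c["r"] is None:
            lines.append(f"  {m}: not evaluable")
        else:
            lines.append(f"  {m}: r={c['r']:.3f} p={c['p']:.2g} n={c['n']}")
    lines += ["", f"Lasso relevance (entry order): {', '.join(rel.entry_order)}",
              f"  relevant at 1-SE penalty: "
              f"{[m for m, v in rel.relevant.items() if v]}"]
    return "\n".join(lines) + "\n"
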