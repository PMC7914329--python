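"""End-to-end experiment orchestration.

A default run enumerates, for every lesion of the cohort, the full grid of

    5 segmentations (4 simulated operators + SAEB)
    x 4 threshold settings (none, 20, 30, 40 % of in-VOI SUVmax)
    x 2 discretizations (AR60 absolute, RR relative)
    = 40 combinations,

extracts the 51 features for each, and evaluates robustness along three
axes:

* **segmentation** — ICC/COV across the 5 delineations at fixed threshold
  and discretization;
* **threshold** — across the 4 threshold settings at fixed segmentation,
  absolute discretization;
* **discretization** — across AR60 vs RR at fixed segmentation, no
  threshold.

Dice overlap is tracked between operator pairs (per threshold) and between
the level-set segmentation and the STAPLE consensus of the four operators
(consensus built from the operators only).  Every stage is deterministic
given the master seed; per-lesion failures are logged and excluded rather
than aborting the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EmptyResultError, LesionRecord, PetradError
from .discretization import DiscretizationSetting
from .features import (
    ALL_FEATURE_NAMES,
    CONVENTIONAL_NAMES,
    HISTOGRAM_NAMES,
    SHAPE_NAMES,
    TEXTURE_NAMES,
    extract_all,
)
from .phantom import PhantomConfig, generate_cohort
from .robustness import (
    RobustnessTable,
    covl,
    dice,
    icc_consistency,
    pearson_profile,
    UndefinedICCError,
)
from .segmentation import SAEBParams, segment_saeb, staple, staple_consensus, threshold_voi

logger = logging.getLogger(__name__)

THRESHOLD_NONE = "none"
FAMILIES = {
    "conventional": CONVENTIONAL_NAMES,
    "histogram": HISTOGRAM_NAMES,
    "shape": SHAPE_NAMES,
    "textural": TEXTURE_NAMES,
}


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    saeb: SAEBParams = field(default_factory=SAEBParams)
    thresholds: tuple = (None, 20, 30, 40)
    discretizations: tuple = (
        DiscretizationSetting(),
        DiscretizationSetting(mode="relative"),
    )
    min_voxels_texture: int = 8
    lifex_small_voi_zero_fill: bool = False
    seed: int | None = None

    def __post_init__(self):
        for t in self.thresholds:
            if t is not None and not 0 < t < 100:
                raise ValueError(f"threshold {t} outside (0, 100)")
        if len(self.discretizations) < 1:
            raise ValueError("need at least one discretization setting")
        if self.seed is not None:
            self.phantom = dataclasses.replace(self.phantom, seed=int(self.seed))

    @property
    def n_combinations(self) -> int:
        n_seg = self.phantom.n_operators + 1  # operators + SAEB
        return n_seg * len(self.thresholds) * len(self.discretizations)


def _threshold_label(t) -> str:
    return THRESHOLD_NONE if t is None else f"{t:g}"


@dataclass
class ExperimentResult:
    """Everything a run produces, ready for summarize()."""

    config: RunConfig
    manifest: pd.DataFrame
    features: pd.DataFrame
    dsc: pd.DataFrame
    robustness: list[RobustnessTable]
    pearson: pd.DataFrame
    exclusions: list[dict]

    def robustness_table(self, axis: str, **fixed) -> RobustnessTable:
        for t in self.robustness:
            if t.axis == axis and all(t.fixed.get(k) == v for k, v in fixed.items()):
                return t
        raise KeyError(f"no robustness table for axis={axis!r}, fixed={fixed!r}")


def _segment_lesion(rec: LesionRecord, cfg: RunConfig) -> tuple[list, dict | None]:
    """Return the 5 segmentation masks for a lesion (SAEB last) and an
    exclusion record if the level set failed."""
    operators = [m for m in rec.delineations if m.label.startswith("operator")]
    masks = list(operators)
    exclusion = None
    seed_pt = tuple(
        int(round(c)) for c in np.argwhere(rec.truth.values).mean(axis=0)
    )
    try:
        masks.append(segment_saeb(rec.image, seed_pt, cfg.saeb))
    except (EmptyResultError, PetradError) as exc:
        logger.warning("SAEB failed on %s: %s", rec.lesion_id, exc)
        exclusion = {"lesion_id": rec.lesion_id, "stage": "saeb", "reason": str(exc)}
    return masks, exclusion


def run_experiment(config: RunConfig | None = None) -> ExperimentResult:
    """Run the full experiment on the (generated) cohort."""
    cfg = config or RunConfig()
    records, manifest = generate_cohort(cfg.phantom)
    feature_rows: list[dict] = []
    dsc_rows: list[dict] = []
    exclusions: list[dict] = []

    for rec in records:
        masks, exclusion = _segment_lesion(rec, cfg)
        if exclusion:
            exclusions.append(exclusion)
        operators = [m for m in masks if m.label.startswith("operator")]
        saeb_mask = next((m for m in masks if m.label == "SAEB"), None)

        consensus = staple_consensus(staple(operators))
        if saeb_mask is not None:
            dsc_rows.append({
                "lesion_id": rec.lesion_id, "comparison": "saeb_vs_staple",
                "threshold": THRESHOLD_NONE,
                "dsc": dice(saeb_mask, consensus),
            })
            for m in operators:
                dsc_rows.append({
                    "lesion_id": rec.lesion_id, "comparison": "saeb_vs_operator",
                    "threshold": THRESHOLD_NONE, "dsc": dice(saeb_mask, m),
                })

        for thr in cfg.thresholds:
            if thr is None:
                thr_ops = operators
            else:
                thr_ops = [threshold_voi(rec.image, m, thr) for m in operators]
            for i in range(len(thr_ops)):
                for j in range(i + 1, len(thr_ops)):
                    dsc_rows.append({
                        "lesion_id": rec.lesion_id, "comparison": "operator_pair",
                        "threshold": _threshold_label(thr),
                        "dsc": dice(thr_ops[i], thr_ops[j]),
                    })

        for mask in masks:
            for thr in cfg.thresholds:
                voi = mask if thr is None else threshold_voi(rec.image, mask, thr)
                for disc in cfg.discretizations:
                    feats = extract_all(
                        rec.image, voi, disc,
                        min_voxels_texture=cfg.min_voxels_texture,
                        lifex_small_voi_zero_fill=cfg.lifex_small_voi_zero_fill,
                    )
                    row = {
                        "lesion_id": rec.lesion_id,
                        "patient_id": rec.patient_id,
                        "segmentation": mask.label,
                        "threshold": _threshold_label(thr),
                        "discretization": disc.name,
                    }
                    row.update(feats)
                    feature_rows.append(row)

    features = pd.DataFrame(feature_rows)
    dsc_df = pd.DataFrame(dsc_rows)
    robustness = _robustness_tables(features, cfg)
    pearson = _pearson_tables(features, manifest, cfg)
    return ExperimentResult(
        config=cfg, manifest=manifest, features=features, dsc=dsc_df,
        robustness=robustness, pearson=pearson, exclusions=exclusions,
    )


def _icc_covl_table(
    sub: pd.DataFrame, axis: str, fixed: dict, method_col: str
) -> RobustnessTable:
    """Build one RobustnessTable from the tidy slice ``sub`` in which
    ``method_col`` enumerates the measurements being compared."""
    table = RobustnessTable(axis=axis, fixed=dict(fixed))
    wide = {
        feat: sub.pivot_table(index="lesion_id", columns=method_col,
                              values=feat, aggfunc="first", dropna=False)
        for feat in ALL_FEATURE_NAMES
    }
    for feat, mat in wide.items():
        arr = mat.to_numpy(dtype=float)
        try:
            table.icc[feat] = icc_consistency(arr)
        except UndefinedICCError:
            continue
        vals = []
        for row in arr:
            if np.isnan(row).any():
                continue
            vals.append(covl(row))
        table.covl_values[feat] = np.asarray(vals, dtype=float)
    return table


def _robustness_tables(features: pd.DataFrame, cfg: RunConfig) -> list[RobustnessTable]:
    tables: list[RobustnessTable] = []
    thr_labels = [_threshold_label(t) for t in cfg.thresholds]
    disc_names = [d.name for d in cfg.discretizations]
    absolute_name = next(
        (d.name for d in cfg.discretizations if d.mode == "absolute"), disc_names[0]
    )
    segs = sorted(features["segmentation"].unique())

    # axis 1: across segmentations, per (threshold, discretization)
    for thr in thr_labels:
        for disc in disc_names:
            sub = features[(features["threshold"] == thr)
                           & (features["discretization"] == disc)]
            tables.append(_icc_covl_table(
                sub, "segmentation", {"threshold": thr, "discretization": disc},
                "segmentation"))

    # axis 2: across thresholds, per segmentation, absolute discretization
    for seg in segs:
        sub = features[(features["segmentation"] == seg)
                       & (features["discretization"] == absolute_name)]
        tables.append(_icc_covl_table(
            sub, "threshold", {"segmentation": seg, "discretization": absolute_name},
            "threshold"))

    # axis 3: across discretizations, per segmentation, no threshold
    if len(disc_names) >= 2:
        for seg in segs:
            sub = features[(features["segmentation"] == seg)
                           & (features["threshold"] == THRESHOLD_NONE)]
            tables.append(_icc_covl_table(
                sub, "discretization", {"segmentation": seg,
                                        "threshold": THRESHOLD_NONE},
                "discretization"))
    return tables


def _pearson_tables(features: pd.DataFrame, manifest: pd.DataFrame,
                    cfg: RunConfig) -> pd.DataFrame:
    """Per-feature Pearson r against segmented volume and SUVmax, feature
    values first averaged across segmentations (no threshold, absolute)."""
    absolute_name = next(
        (d.name for d in cfg.discretizations if d.mode == "absolute"),
        cfg.discretizations[0].name,
    )
    sub = features[(features["threshold"] == THRESHOLD_NONE)
                   & (features["discretization"] == absolute_name)].copy()
    per_lesion = sub.groupby("lesion_id")[list(ALL_FEATURE_NAMES)].mean()
    refs = per_lesion[["SHAPE_Volume_mL", "CONV_SUVmax"]].rename(
        columns={"SHAPE_Volume_mL": "volume", "CONV_SUVmax": "suvmax"})
    tbl = per_lesion.join(refs).reset_index()
    r_vol = pearson_profile(tbl, "volume", feature_columns=list(ALL_FEATURE_NAMES))
    r_suv = pearson_profile(tbl, "suvmax", feature_columns=list(ALL_FEATURE_NAMES))
    return pd.DataFrame({"r_volume": r_vol, "r_suvmax": r_suv})


# ---------------------------------------------------------------------------
# summaries and reports
# ---------------------------------------------------------------------------

def median_icc_across(tables: list[RobustnessTable]) -> dict[str, float]:
    """Per-feature median ICC over a set of robustness tables (e.g. the
    per-operator threshold-axis tables)."""
    out = {}
    for feat in ALL_FEATURE_NAMES:
        vals = [t.icc[feat].icc for t in tables if feat in t.icc]
        out[feat] = float(np.median(vals)) if vals else float("nan")
    return out


def high_icc_fraction(icc_by_feature: dict[str, float]) -> float:
    vals = [v for v in icc_by_feature.values() if np.isfinite(v)]
    if not vals:
        return float("nan")
    return float(np.mean([v > 0.9 for v in vals]))


def _family_counts(icc_by_feature: dict[str, float]) -> dict[str, str]:
    out = {}
    for fam, names in FAMILIES.items():
        vals = [icc_by_feature.get(n, float("nan")) for n in names]
        defined = [v for v in vals if np.isfinite(v)]
        out[fam] = f"{sum(v > 0.9 for v in defined)}/{len(defined)}"
    return out


def summarize(result: ExperimentResult, outdir, plots: bool = False) -> dict:
    """Write the report files and return the headline summary dict.

    Outputs: ``features.csv`` (tidy feature table), ``dsc.csv`` and
    ``dsc_summary.csv``, ``robustness.csv``, ``pearson.csv`` and
    ``summary.json``; with ``plots=True`` also boxplot/bar figures (every
    figure has a CSV twin, so numbers are always testable).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False)
    result.manifest.to_csv(out / "manifest.csv", index=False)
    result.dsc.to_csv(out / "dsc.csv", index=False)
    dsc_summary = (
        result.dsc.groupby(["comparison", "threshold"])["dsc"]
        .agg(["mean", "std", "min", "max", "count"]).reset_index()
    )
    dsc_summary.to_csv(out / "dsc_summary.csv", index=False)
    rob = pd.concat([t.to_frame() for t in result.robustness], ignore_index=True)
    rob.to_csv(out / "robustness.csv", index=False)
    result.pearson.to_csv(out / "pearson.csv", index=True, index_label="feature")

    cfg = result.config
    absolute_name = next(
        (d.name for d in cfg.discretizations if d.mode == "absolute"),
        cfg.discretizations[0].name,
    )
    seg_none = result.robustness_table(
        "segmentation", threshold=THRESHOLD_NONE, discretization=absolute_name)
    seg_icc_none = {f: r.icc for f, r in seg_none.icc.items()}
    thr_tables = [t for t in result.robustness if t.axis == "threshold"]
    disc_tables = [t for t in result.robustness if t.axis == "discretization"]
    thr_icc = median_icc_across(thr_tables)
    disc_icc = median_icc_across(disc_tables)

    seg_fractions = {}
    for thr in [_threshold_label(t) for t in cfg.thresholds]:
        t = result.robustness_table("segmentation", threshold=thr,
                                    discretization=absolute_name)
        seg_fractions[thr] = high_icc_fraction({f: r.icc for f, r in t.icc.items()})

    op_dsc = result.dsc[(result.dsc.comparison == "operator_pair")
                        & (result.dsc.threshold == THRESHOLD_NONE)]["dsc"]
    sv_dsc = result.dsc[result.dsc.comparison == "saeb_vs_staple"]["dsc"]

    summary = {
        "n_lesions": int(result.manifest.shape[0]),
        "n_feature_rows": int(result.features.shape[0]),
        "n_combinations_per_lesion": int(cfg.n_combinations),
        "n_features": len(ALL_FEATURE_NAMES),
        "exclusions": result.exclusions,
        "dsc_operator_pairs_mean": float(op_dsc.mean()),
        "dsc_operator_pairs_sd": float(op_dsc.std()),
        "dsc_saeb_vs_staple_mean": float(sv_dsc.mean()) if len(sv_dsc) else float("nan"),
        "dsc_saeb_vs_staple_sd": float(sv_dsc.std()) if len(sv_dsc) else float("nan"),
        "high_icc_fraction_segmentation_by_threshold": seg_fractions,
        "high_icc_fraction_threshold_axis": high_icc_fraction(thr_icc),
        "high_icc_fraction_discretization_axis": high_icc_fraction(disc_icc),
        "family_high_counts_segmentation_none": _family_counts(seg_icc_none),
        "family_high_counts_discretization": _family_counts(disc_icc),
        "pearson_tlsre_volume": float(result.pearson.loc["CONV_TLSRE", "r_volume"]),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    if plots:
        _write_plots(result, out / "plots")
    return summary


def _write_plots(result: ExperimentResult, plotdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotdir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 4))
    groups, labels = [], []
    for (comp, thr), g in result.dsc.groupby(["comparison", "threshold"]):
        groups.append(g["dsc"].dropna().to_numpy())
        labels.append(f"{comp}\n@{thr}")
    ax.boxplot(groups, tick_labels=labels)
    ax.set_ylabel("Dice similarity coefficient")
    fig.autofmt_xdate(rotation=45)
    fig.tight_layout()
    fig.savefig(plotdir / "dsc_boxplots.png", dpi=120)
    plt.close(fig)

    for table in result.robustness[:2]:
        feats = list(table.icc)
        vals = [table.icc[f].icc for f in feats]
        fig, ax = plt.subplots(figsize=(10, 4))
        ax.bar(range(len(feats)), vals)
        ax.set_xticks(range(len(feats)))
        ax.set_xticklabels(feats, rotation=90, fontsize=5)
        ax.axhline(0.9, color="r", ls="--", lw=0.8)
        ax.set_ylabel("ICC")
        ax.set_title(f"axis={table.axis} {table.fixed}")
        fig.tight_layout()
        fig.savefig(plotdir / f"icc_{table.axis}_{'_'.join(map(str, table.fixed.values()))}.png",
                    dpi=120)
        plt.close(fig)
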