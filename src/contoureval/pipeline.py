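"""End-to-end cohort evaluation: geometry, dosimetry on the fixed plan, statistics.

The protocol mirrors how auto-segmentation is evaluated clinically:
the dose distribution is computed once from the manual contours and then
*frozen*; auto contours are only ever swapped into that fixed dose grid,
never used to re-plan. Section 1 scores contour geometry (DSC / JC /
HD / 95%HD), Section 2 recomputes the dose–volume indices of record for
both contour sets, Section 3 tests paired differences (Wilcoxon),
agreement (Bland–Altman) and the correlation between geometric accuracy
and dose differences (Spearman).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dosimetry import evaluate_dosimetry
from .geometry import evaluate_geometry
from .grids import METRICS_OF_RECORD, BinaryMask, PlanConfig, StructureSet, VolumeGrid
from .io import read_volume, write_labelmap, write_volume
from .phantoms import (
    PerturbationSpec,
    PhantomCase,
    default_perturbation_profile,
    generate_cohort,
)
from .stats import bland_altman, correlation_table, delta_dose, wilcoxon_signed_rank


@dataclass
class RunConfig:
    """Configuration for one cohort evaluation run.

    Exactly one cohort source: generate (n_cases + seed) or load
    (cohort_dir). Exactly one auto-contour source: the cohort's stored
    perturbation arm, or a segmenter checkpoint applied to the images.
    """

    n_cases: int = 30
    seed: int = 0
    cohort_dir: str | None = None
    auto_source: str = "perturbation"  # or a model checkpoint path
    perturbation: PerturbationSpec | None = None
    plan: PlanConfig = field(default_factory=PlanConfig)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.cohort_dir is not None and self.n_cases is None:
            raise ValueError("choose one cohort source: generate (n_cases) or load (cohort_dir)")


@dataclass
class ComparisonReport:
    """All per-case tables and cohort statistics from one evaluation run."""

    geometry: pd.DataFrame  # case_id, structure, dsc, jc, hd_mm, hd95_mm, status
    dvi: pd.DataFrame  # case_id, structure, provenance, metric, value, constraint...
    table2: pd.DataFrame  # paired summary: mean±SD both arms, Wilcoxon Z/P, BA
    table3: pd.DataFrame  # Spearman r/P per structure x delta-metric x geo-metric
    bland_altman_points: pd.DataFrame  # per-case (mean, difference) with limits
    heatmap: pd.DataFrame  # structures x geometric metrics matrix of r
    metadata: dict

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.geometry.to_csv(outdir / "geometry.csv", index=False)
        self.dvi.to_csv(outdir / "dvi.csv", index=False)
        self.table2.to_csv(outdir / "paired_dose_summary.csv", index=False)
        self.table3.to_csv(outdir / "correlations.csv", index=False)
        self.bland_altman_points.to_csv(outdir / "bland_altman.csv", index=False)
        self.heatmap.to_csv(outdir / "correlation_heatmap.csv")
        (outdir / "run_metadata.json").write_text(json.dumps(self.metadata, indent=2))
        (outdir / "summary.md").write_text(self.summary_markdown())

    def summary_markdown(self) -> str:
        lines = ["# Contour evaluation summary", ""]
        ok = self.geometry[self.geometry["status"] == "ok"]
        g = ok.groupby("structure")[["dsc", "jc", "hd95_mm"]].agg(["mean", "std"])
        lines.append(f"Cases: {self.metadata.get('n_cases')}  |  "
                     f"auto source: {self.metadata.get('auto_source')}")
        lines.append("")
        lines.append("## Geometric accuracy (mean ± SD)")
        lines.append("")
        lines.append("| structure | DSC | JC | 95%HD (mm) |")
        lines.append("|---|---|---|---|")
        for s in g.index:
            lines.append(
                f"| {s} | {g.loc[s, ('dsc', 'mean')]:.3f} ± {g.loc[s, ('dsc', 'std')]:.3f} "
                f"| {g.loc[s, ('jc', 'mean')]:.3f} ± {g.loc[s, ('jc', 'std')]:.3f} "
                f"| {g.loc[s, ('hd95_mm', 'mean')]:.2f} ± {g.loc[s, ('hd95_mm', 'std')]:.2f} |")
        lines.append("")
        lines.append("## Paired dose–volume indices")
        lines.append("")
        lines.append("| structure | metric | manual | auto | Z | P |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in self.table2.iterrows():
            lines.append(
                f"| {r['structure']} | {r['metric']} "
                f"| {r['manual_mean']:.2f} ± {r['manual_sd']:.2f} "
                f"| {r['auto_mean']:.2f} ± {r['auto_sd']:.2f} "
                f"| {r['z']:.2f} | {r['p']:.3g} |")
        strong = self.table3[self.table3["strong"] == True]  # noqa: E712
        lines.append("")
        if len(strong):
            lines.append("Strong correlations (|r| >= 0.8):")
            for _, r in strong.iterrows():
                lines.append(f"- {r['structure']} {r['delta_metric']} vs "
                             f"{r['geometric_metric']}: r = {r['r']:.3f}, P = {r['p_value']:.3g}")
        else:
            lines.append("No strong correlations (|r| >= 0.8).")
        lines.append("")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# cohort persistence (NIfTI volumes + labelmaps + JSON plan per case)


def save_cohort(cases: list[PhantomCase], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        cdir = outdir / case.case_id
        cdir.mkdir(exist_ok=True)
        names = case.manual.names()
        write_volume(case.image, cdir / "image.nii.gz")
        write_volume(case.dose, cdir / "dose.nii.gz")
        write_labelmap(case.manual, cdir / "manual_labels.nii.gz", names)
        # auto contours may overlap (independent perturbations), so a single
        # labelmap would be lossy; store one binary mask per structure
        g = case.auto.geometry
        for i, n in enumerate(names):
            if n in case.auto:
                mask_grid = VolumeGrid(case.auto[n].voxels.astype(np.uint8),
                                       g.spacing, g.origin)
                write_volume(mask_grid, cdir / f"auto_{i:02d}.nii.gz")
        case.plan.to_json(cdir / "plan.json")
        (cdir / "structures.json").write_text(json.dumps(names))
        rows.append(dict(case_id=case.case_id, n_structures=len(names)))
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)


def load_cohort(indir: str | Path) -> list[PhantomCase]:
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    cases = []
    for case_id in manifest["case_id"]:
        cdir = indir / case_id
        names = json.loads((cdir / "structures.json").read_text())
        image = read_volume(cdir / "image.nii.gz", "image")
        dose = read_volume(cdir / "dose.nii.gz", "dose")
        manual = read_volume(cdir / "manual_labels.nii.gz", "labelmap", names, "manual")
        geom = manual.geometry
        auto_masks = {}
        for i, n in enumerate(names):
            p = cdir / f"auto_{i:02d}.nii.gz"
            if p.exists():
                auto_masks[n] = BinaryMask(geom, read_volume(p, "image").values > 0)
        auto = StructureSet(auto_masks, provenance="auto")
        plan = PlanConfig.from_json(cdir / "plan.json")
        cases.append(PhantomCase(case_id, image, manual, auto, dose, plan))
    return cases


# ---------------------------------------------------------------------------


def _auto_sets(config: RunConfig, cases: list[PhantomCase]) -> dict[str, StructureSet]:
    if config.auto_source == "perturbation":
        return {c.case_id: c.auto for c in cases}
    from .network import EncoderDecoder, segment  # deferred: only for checkpoints

    model = EncoderDecoder.load(config.auto_source)
    return {c.case_id: segment(model, c.image, c.manual.names()) for c in cases}


def evaluate_cohort(cases: list[PhantomCase],
                    auto_sets: dict[str, StructureSet] | None = None,
                    metrics_of_record: dict | None = None,
                    metadata: dict | None = None) -> ComparisonReport:
    """Run all three evaluation sections over an in-memory cohort."""
    mor = metrics_of_record or dict(METRICS_OF_RECORD)
    geom_rows, dvi_rows = [], []
    for case in cases:
        auto = auto_sets[case.case_id] if auto_sets else case.auto
        g = evaluate_geometry(case.manual, auto)
        g.insert(0, "case_id", case.case_id)
        geom_rows.append(g)
        d = evaluate_dosimetry(case.dose, case.manual, auto, case.plan)
        d.insert(0, "case_id", case.case_id)
        dvi_rows.append(d)
    geometry = pd.concat(geom_rows, ignore_index=True)
    dvi = pd.concat(dvi_rows, ignore_index=True)

    deltas = delta_dose(dvi)
    table2_rows, ba_points = [], []
    for structure, metrics in mor.items():
        for metric in metrics:
            sub = deltas[(deltas["structure"] == structure) & (deltas["metric"] == metric)]
            if len(sub) < 3:
                continue
            m = sub["manual"].to_numpy()
            a = sub["auto"].to_numpy()
            try:
                w = wilcoxon_signed_rank(m, a)
            except ValueError:
                # fewer than 5 nonzero differences: not enough pairs to test
                from .stats import PairedTestResult

                w = PairedTestResult(np.nan, np.nan, len(m),
                                     int(np.count_nonzero(a - m)))
            ba = bland_altman(m, a)
            table2_rows.append(dict(
                structure=structure, metric=metric,
                manual_mean=m.mean(), manual_sd=m.std(ddof=1),
                auto_mean=a.mean(), auto_sd=a.std(ddof=1),
                z=w.z_statistic, p=w.p_value, significant=w.significant,
                no_difference=w.no_difference,
                ba_bias=ba.bias, ba_loa_low=ba.loa_low, ba_loa_high=ba.loa_high,
                ba_n_outside=ba.n_outside, ba_p=ba.p_bias,
                ba_applicable=ba.applicable, ba_agreement=ba.agreement,
            ))
            pts = pd.DataFrame(dict(
                case_id=sub["case_id"], structure=structure, metric=metric,
                pair_mean=(m + a) / 2.0, difference=a - m,
            ))
            pts["bias"], pts["loa_low"], pts["loa_high"] = ba.bias, ba.loa_low, ba.loa_high
            ba_points.append(pts)
    table2 = pd.DataFrame(table2_rows)
    ba_df = (pd.concat(ba_points, ignore_index=True) if ba_points
             else pd.DataFrame(columns=["case_id", "structure", "metric", "pair_mean",
                                        "difference", "bias", "loa_low", "loa_high"]))

    geo_ok = geometry[geometry["status"] == "ok"]
    table3, heat = correlation_table(geo_ok, deltas, mor)

    meta = dict(metadata or {})
    meta.setdefault("n_cases", len(cases))
    meta.setdefault("auto_source", "perturbation" if auto_sets is None else "provided")
    meta["package_version"] = __version__
    meta["structures"] = cases[0].manual.names() if cases else []
    return ComparisonReport(geometry, dvi, table2, table3, ba_df, heat, meta)


def run_evaluation(config: RunConfig) -> ComparisonReport:
    """Execute the full three-section evaluation defined by *config*."""
    if config.cohort_dir is not None:
        cases = load_cohort(config.cohort_dir)
        cohort_meta = dict(cohort_source=str(config.cohort_dir))
    else:
        spec = config.perturbation or default_perturbation_profile()
        cases = generate_cohort(config.n_cases, config.seed, spec, plan=config.plan)
        cohort_meta = dict(cohort_source="generated", seed=config.seed)
    auto_sets = _auto_sets(config, cases)
    meta = dict(cohort_meta, n_cases=len(cases), auto_source=config.auto_source,
                prescription_cGy=config.plan.prescription_cGy,
                config=json.loads(json.dumps(dataclasses.asdict(config), default=str)))
    report = evaluate_cohort(cases, auto_sets, metadata=meta)
    if config.output_dir is not None:
        report.save(config.output_dir)
    return report
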