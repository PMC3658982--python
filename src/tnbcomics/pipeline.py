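"""End-to-end orchestration of the multi-omic analysis stages.

``run_pipeline`` drives simulate/ingest -> copy-number segmentation and
calling -> expression preprocessing -> RPPA normalisation -> cross-layer
concordance -> survival analysis -> report, under one config with
deterministic seeding (a single seed fanned out to per-stage children, so
disabling one stage never shifts another stage's randomness) and a manifest
recording parameters and input hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .cna import (GenomicInterval, calibrate_thresholds, call_cna,
                  gain_frequency_by_group, locus_amplitude)
from .expression import (OmicsMatrix, adjust_batch, average_replicates,
                         differential_expression, noise_floor_filter)
from .integration import layer_concordance_report
from .rppa import differential_abundance, normalize_rppa
from .segmentation import run_two_round
from .survival import prognosis_report
from .synthetic import (DRIVER_ARRAY, DRIVER_GENE, PROLIFERATION_MARKER,
                        CohortDesign, SyntheticCohort, simulate_cohort)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "build_report"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    With ``simulate=True`` the synthetic generator provides every input;
    otherwise the four input paths must point to existing TSV tables
    (validated before any stage executes).
    """

    seed: int = 0
    out_dir: str | None = None
    simulate: bool = True
    design: dict = field(default_factory=dict)
    n_probes: int = 500
    n_genes: int = 200
    n_arrays: int = 27
    n_dilutions: int = 5
    tracks_path: str | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    rppa_path: str | None = None
    survival_path: str | None = None
    locus: dict | None = None
    stages: dict = field(default_factory=lambda: {
        "cna": True, "expression": True, "rppa": True,
        "integration": True, "survival": True,
    })
    penalty: str | float = "auto"
    min_seg_probes: int = 5
    filter_threshold: float = 4.0
    filter_fraction: float = 0.95
    gain_quantile: float = 0.999
    loss_quantile: float = 0.001
    endpoints: tuple[str, ...] = ("OS", "DFI", "metastasis")
    survival_subgroup: str = "TNBC"
    write_outputs: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            paths = {
                "tracks_path": self.tracks_path,
                "expression_path": self.expression_path,
                "annotation_path": self.annotation_path,
                "rppa_path": self.rppa_path,
                "survival_path": self.survival_path,
            }
            missing = [k for k, v in paths.items()
                       if v is None or not Path(v).exists()]
            if missing:
                raise FileNotFoundError(
                    f"pipeline inputs unresolvable before execution: {missing}")

    def build_design(self) -> CohortDesign:
        kwargs = dict(self.design)
        kwargs.setdefault("seed", self.seed)
        if "batch_offsets" in kwargs:
            kwargs["batch_offsets"] = tuple(kwargs["batch_offsets"])
        return CohortDesign(**kwargs)


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: SyntheticCohort | None
    segmentations: dict
    thresholds: tuple[float, float] | None
    locus_calls: dict
    gain_fractions: dict
    fisher_table: pd.DataFrame | None
    expression_processed: OmicsMatrix | None
    discarded_features: list
    expression_differential: pd.DataFrame | None
    rppa_normalized: object
    rppa_differential: pd.DataFrame | None
    concordance: pd.DataFrame | None
    survival_table: pd.DataFrame | None
    subgroup_means: dict
    protein_means: dict
    manifest: dict

    def summary(self) -> str:
        return build_report(self)


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every enabled stage in dependency order.

    Identical config + seed give byte-identical numeric outputs.  Any stage
    error aborts with the stage name attached.
    """
    config.validate()
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {}}
    out = Path(config.out_dir) if (config.out_dir and config.write_outputs) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        if config.simulate:
            design = config.build_design()
            locus = (GenomicInterval(**config.locus) if config.locus else None)
            cohort = simulate_cohort(design, n_probes=config.n_probes,
                                     n_genes=config.n_genes,
                                     n_arrays=config.n_arrays,
                                     n_dilutions=config.n_dilutions,
                                     locus=locus, seed=config.seed)
            tracks = cohort.tracks
            expr_raw = cohort.expression
            rppa_table = cohort.rppa
            surv = cohort.survival
            locus = cohort.locus
            annotations = expr_raw.sample_info["subgroup"]
            manifest["inputs"]["design"] = asdict(design)
        else:
            cohort = None
            tracks = tio.read_probe_tracks(config.tracks_path)
            expr_raw = tio.read_omics_matrix(config.expression_path,
                                             config.annotation_path)
            rppa_table = tio.read_rppa_table(config.rppa_path)
            surv = tio.read_survival(config.survival_path)
            annotations = expr_raw.sample_info["subgroup"]
            locus = GenomicInterval(**config.locus) if config.locus else None
            for key in ("tracks_path", "expression_path", "annotation_path",
                        "rppa_path", "survival_path"):
                p = getattr(config, key)
                manifest["inputs"][key] = hashlib.sha256(
                    Path(p).read_bytes()).hexdigest()[:16]
        if out:
            tio.write_probe_tracks(tracks, out / "probe_tracks.tsv")
            tio.write_omics_matrix(expr_raw, out / "expression.tsv",
                                   out / "annotations.tsv")
            tio.write_rppa_table(rppa_table, out / "rppa.tsv")
            tio.write_survival(surv, out / "survival.tsv")

        segmentations: dict = {}
        thresholds = None
        locus_calls: dict = {}
        gain_fractions: dict = {}
        fisher = None
        cn_amplitude: dict = {}
        if config.stages.get("cna", True):
            stage = "cna"
            for sample_id, track in tracks.items():
                segmentations[sample_id] = run_two_round(
                    track, penalty=config.penalty,
                    min_probes=config.min_seg_probes)
            healthy = [s for s in tracks
                       if annotations.get(s, "") == "healthy"]
            pool = np.concatenate([segmentations[s].smoothed for s in healthy]) \
                if healthy else np.concatenate(
                    [segmentations[s].smoothed for s in tracks])
            thresholds = calibrate_thresholds(pool, config.gain_quantile,
                                              config.loss_quantile)
            tumor_samples = [s for s in tracks if s not in healthy]
            for s in tumor_samples:
                calls = call_cna(segmentations[s], thresholds,
                                 track=tracks[s],
                                 loci={"driver": locus} if locus else None)
                locus_calls[s] = calls.locus_calls.get("driver", 0)
                if locus is not None:
                    cn_amplitude[s] = locus_amplitude(segmentations[s],
                                                      tracks[s], locus)
            gain_fractions, fisher = gain_frequency_by_group(
                locus_calls, dict(annotations[tumor_samples]))
            manifest["stages"]["cna"] = {
                "penalty": config.penalty,
                "thresholds": list(thresholds),
                "n_samples": len(segmentations),
            }
            if out:
                tio.write_seg({s: (tracks[s], segmentations[s])
                               for s in segmentations}, out / "segments.seg")
                fisher.to_csv(out / "gain_fisher.tsv", sep="\t", index=False)

        expr_processed = None
        discarded: list = []
        expr_diff = None
        subgroup_means: dict = {}
        if config.stages.get("expression", True):
            stage = "expression"
            m = average_replicates(expr_raw)
            m = adjust_batch(m)
            m, discarded_idx = noise_floor_filter(
                m, config.filter_threshold, config.filter_fraction)
            discarded = list(discarded_idx)
            expr_processed = m
            subgroup_means = {
                g: float(m.values.loc[DRIVER_GENE, m.samples_in(g)].mean())
                for g in sorted(m.sample_info["subgroup"].unique())
                if DRIVER_GENE in m.values.index and len(m.samples_in(g))
            }
            diffs = []
            groups = sorted(g for g in m.sample_info["subgroup"].unique()
                            if g != "TNBC")
            for g in groups:
                if len(m.samples_in(g)) < 2 or len(m.samples_in("TNBC")) < 2:
                    continue
                d = differential_expression(m, "TNBC", g)
                d = d.assign(comparison=f"TNBC_vs_{g}")
                diffs.append(d.loc[[DRIVER_GENE]] if DRIVER_GENE in d.index else d)
            expr_diff = pd.concat(diffs) if diffs else None
            manifest["stages"]["expression"] = {
                "n_discarded": len(discarded),
                "n_retained": m.n_features,
            }
            if out:
                tio.write_omics_matrix(m, out / "expression_processed.tsv",
                                       out / "annotations_processed.tsv")
                pd.Series(discarded, name="feature_id").to_frame().assign(
                    reason="noise_floor").to_csv(
                    out / "discarded_features.tsv", sep="\t", index=False)

        rppa_norm = None
        rppa_diff = None
        protein_means: dict = {}
        if config.stages.get("rppa", True):
            stage = "rppa"
            norm_groups = normalize_rppa(rppa_table)
            rppa_norm = norm_groups.get("tumor", next(iter(norm_groups.values())))
            if DRIVER_ARRAY in rppa_norm.values.index:
                row = rppa_norm.values.loc[DRIVER_ARRAY]
                protein_means = {
                    g: float(row[[s for s in row.index
                                  if annotations.get(s) == g]].mean())
                    for g in sorted(set(annotations[row.index.intersection(
                        annotations.index)]))
                }
                rows = []
                for g in sorted(set(annotations[row.index])):
                    if g in ("TNBC",):
                        continue
                    res = differential_abundance(rppa_norm, DRIVER_ARRAY,
                                                 annotations, "TNBC", g)
                    rows.append({"comparison": f"TNBC_vs_{g}", "t": res.t,
                                 "p": res.p, "df": res.df,
                                 "mean_tnbc": res.mean_a, "mean_other": res.mean_b})
                rppa_diff = pd.DataFrame(rows)
            manifest["stages"]["rppa"] = {
                "groups": sorted(norm_groups),
                "n_arrays": int(rppa_norm.values.shape[0]),
            }
            if out:
                rppa_norm.values.to_csv(out / "rppa_normalized.tsv", sep="\t")
                pd.DataFrame({
                    "median": rppa_norm.per_array_median,
                    "mad": rppa_norm.per_array_mad,
                    "slope_pre": rppa_norm.loading_slopes_pre,
                    "slope_post": rppa_norm.loading_slopes_post,
                }).to_csv(out / "rppa_diagnostics.tsv", sep="\t",
                          index_label="array_id")

        concordance = None
        if config.stages.get("integration", True):
            stage = "integration"
            layers: dict[str, pd.Series] = {}
            if expr_processed is not None and DRIVER_GENE in expr_processed.values.index:
                layers["mRNA"] = expr_processed.values.loc[DRIVER_GENE]
                if PROLIFERATION_MARKER in expr_processed.values.index:
                    layers["proliferation_mRNA"] = \
                        expr_processed.values.loc[PROLIFERATION_MARKER]
            if rppa_norm is not None and DRIVER_ARRAY in rppa_norm.values.index:
                layers["protein"] = rppa_norm.values.loc[DRIVER_ARRAY]
            if cn_amplitude:
                layers["copy_number"] = pd.Series(cn_amplitude)
            pairs = [p for p in (("mRNA", "protein"), ("mRNA", "copy_number"),
                                 ("protein", "proliferation_mRNA"))
                     if p[0] in layers and p[1] in layers]
            if len(layers) >= 2 and pairs:
                concordance = layer_concordance_report(layers, annotations,
                                                       pairs=pairs)
                # pairs missing a layer (e.g. CNA stage disabled) are reported
                # as not computed rather than dropped silently
                for a, b in (("mRNA", "protein"), ("mRNA", "copy_number"),
                             ("protein", "proliferation_mRNA")):
                    if (a, b) not in pairs:
                        concordance = pd.concat([concordance, pd.DataFrame([{
                            "pair": f"{a}~{b}", "stratum": "all", "n": 0,
                            "rho": float("nan"), "p": float("nan"),
                            "computed": False}])], ignore_index=True)
            manifest["stages"]["integration"] = {
                "pairs": [f"{a}~{b}" for a, b in pairs]}
            if out and concordance is not None:
                concordance.to_csv(out / "concordance.tsv", sep="\t", index=False)

        survival_table = None
        if config.stages.get("survival", True) and expr_processed is not None \
                and DRIVER_GENE in expr_processed.values.index:
            stage = "survival"
            survival_table = prognosis_report(
                expr_processed.values.loc[DRIVER_GENE], surv,
                annotations=annotations, subgroup=config.survival_subgroup,
                endpoints=list(config.endpoints))
            manifest["stages"]["survival"] = {
                "subgroup": config.survival_subgroup,
                "endpoints": list(config.endpoints),
            }
            if out:
                survival_table.to_csv(out / "survival_results.tsv",
                                      sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    result = PipelineResult(
        config=config, cohort=cohort, segmentations=segmentations,
        thresholds=thresholds, locus_calls=locus_calls,
        gain_fractions=gain_fractions, fisher_table=fisher,
        expression_processed=expr_processed, discarded_features=discarded,
        expression_differential=expr_diff, rppa_normalized=rppa_norm,
        rppa_differential=rppa_diff, concordance=concordance,
        survival_table=survival_table, subgroup_means=subgroup_means,
        protein_means=protein_means, manifest=manifest,
    )
    if out:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        with open(out / "report.txt", "w") as fh:
            fh.write(build_report(result))
    return result


def _fmt(x) -> str:
    return "NA" if x is None or (isinstance(x, float) and not np.isfinite(x)) \
        else (f"{x:.4g}" if isinstance(x, float) else str(x))


def build_report(result: PipelineResult) -> str:
    """Human-readable run summary assembled purely from stage artifacts."""
    if not any([result.subgroup_means, result.gain_fractions,
                result.protein_means, result.concordance is not None,
                result.survival_table is not None]):
        raise ValueError("no stage artifacts to report")
    lines = ["# Multi-omic driver-gene report", ""]
    if result.subgroup_means:
        lines.append("## Driver mRNA mean log2 by subgroup")
        for g, v in sorted(result.subgroup_means.items(),
                           key=lambda kv: -kv[1]):
            lines.append(f"  {g}: {_fmt(v)}")
        lines.append("")
    if result.protein_means:
        lines.append("## Driver protein (normalised RPPA) mean by subgroup")
        for g, v in sorted(result.protein_means.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {g}: {_fmt(v)}")
        lines.append("")
    if result.gain_fractions:
        lines.append("## Locus gain frequency by subgroup")
        for g, v in sorted(result.gain_fractions.items(), key=lambda kv: -kv[1]):
            lines.append(f"  {g}: {_fmt(v)}")
        if result.fisher_table is not None and len(result.fisher_table):
            for _, r in result.fisher_table.iterrows():
                lines.append(f"  Fisher {r.group_a} vs {r.group_b}: "
                             f"p = {_fmt(float(r.fisher_p))}")
        lines.append("")
    if result.rppa_differential is not None and len(result.rppa_differential):
        lines.append("## Protein differential abundance (Welch t)")
        for _, r in result.rppa_differential.iterrows():
            lines.append(f"  {r.comparison}: t = {_fmt(float(r.t))}, "
                         f"p = {_fmt(float(r.p))}")
        lines.append("")
    if result.concordance is not None:
        lines.append("## Cross-layer Spearman concordance")
        for _, r in result.concordance.iterrows():
            if r.stratum in ("all", "TNBC"):
                tag = "" if r.computed else " (not computed)"
                lines.append(f"  {r.pair} [{r.stratum}] n={r.n}: "
                             f"rho = {_fmt(float(r.rho))}, p = {_fmt(float(r.p))}{tag}")
        lines.append("")
    if result.survival_table is not None:
        lines.append("## Survival (continuous Cox + median-split logrank)")
        for _, r in result.survival_table.iterrows():
            lines.append(
                f"  {r.endpoint}: HR = {_fmt(float(r.hazard_ratio))} "
                f"[{_fmt(float(r.ci_low))}, {_fmt(float(r.ci_high))}], "
                f"Wald p = {_fmt(float(r.wald_p))}, "
                f"logrank p = {_fmt(float(r.logrank_p))}"
                + ("" if r.computed else " (not computed)"))
        lines.append("")
    if result.expression_processed is not None:
        lines.append(f"## Noise filter: {len(result.discarded_features)} "
                     f"features discarded, "
                     f"{result.expression_processed.n_features} retained")
    return "\n".join(lines) + "\n"
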