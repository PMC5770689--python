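"""End-to-end pipeline: differential calling -> targeting -> UTR features
-> folding -> group comparison -> (optional) metabolite screen.

The driver reads the input tables, runs every stage with one configuration
object, writes per-stage TSVs with provenance headers into the output
directory and returns (and writes) a single JSON report with all
summaries. Output is deterministic for a fixed seed; any stage failure
aborts before partial results of later stages are written.
"""

from __future__ import annotations

import functools
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexp, fold, groupstats, io, metabolome, targeting, utr
from ._version import __version__

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    quant_path: str
    flags_path: str
    fasta_path: str
    ann_path: str
    out_dir: str
    peaks_path: str | None = None
    meta_path: str | None = None
    alpha: float = 0.05
    min_reps: int = 3
    min_utr_length: int = 13
    fold_enabled: bool = True
    fold_max_len: int = 1000
    length_edges: tuple[float, ...] = field(default_factory=lambda: groupstats.LENGTH_EDGES)
    stat_method: str = "permutation"
    n_perm: int = 2000
    seed: int = 0

    def input_paths(self) -> list[str]:
        paths = [self.quant_path, self.flags_path, self.fasta_path, self.ann_path]
        if self.peaks_path:
            paths += [self.peaks_path, self.meta_path or ""]
        return paths


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and return the integrated report."""
    for path in config.input_paths():
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"pipeline input not found: {path!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "config": asdict(config),
        }
    }

    # 1. differential synthesis calling
    quant = io.read_quant_table(config.quant_path)
    oriented = diffexp.orient_ratios(quant)
    kept, filtered = diffexp.filter_detected(oriented, config.min_reps)
    results = diffexp.test_differential(kept, config.alpha) + filtered
    io.write_tsv(
        out / "differential.tsv", diffexp.results_to_frame(results), "diffexp",
        config.seed, alpha=config.alpha, min_reps=config.min_reps,
    )
    report["differential"] = diffexp.summarize_regulation(results)

    groups: dict[str, set[str]] = {}
    for r in results:
        if r.status == "up":
            groups[r.protein_id] = {"all", "regulated", "upregulated"}
        elif r.status == "down":
            groups[r.protein_id] = {"all", "regulated", "downregulated"}
        elif r.status in ("ns", "degenerate"):
            groups[r.protein_id] = {"all", "non-regulated"}

    # 2. secretory-pathway targeting enrichment
    annotations = io.read_annotations(config.flags_path)
    annotations = [a for a in annotations if a.protein_id in groups]
    order = ["all", "regulated", "upregulated", "downregulated", "non-regulated"]
    summaries = targeting.summarize_targeting(annotations, groups, group_order=order)
    by_label = {s.group_label: s for s in summaries}
    reg, non = by_label["regulated"], by_label["non-regulated"]
    chi2_stat, chi2_p = (float("nan"), float("nan"))
    if reg.n and non.n:
        chi2_stat, chi2_p = targeting.chi_square_test(
            [
                [reg.n_targeting, reg.n - reg.n_targeting],
                [non.n_targeting, non.n - non.n_targeting],
            ]
        )
    report["targeting"] = {
        "groups": {
            s.group_label: {
                "n": s.n, "n_sp": s.n_sp, "n_tm": s.n_tm, "n_both": s.n_both,
                "n_targeting": s.n_targeting, "pct_sp": s.pct_sp,
                "pct_tm": s.pct_tm, "pct_targeting": s.pct_targeting,
            }
            for s in summaries
        },
        "chi2_targeting_regulated_vs_nonregulated": {"stat": chi2_stat, "p": chi2_p},
    }
    io.write_tsv(
        out / "targeting.tsv",
        pd.DataFrame(
            [
                (s.group_label, s.n, s.n_sp, s.n_tm, s.n_both, s.n_targeting,
                 s.pct_sp, s.pct_tm, s.pct_targeting)
                for s in summaries
            ],
            columns=["group", "n", "n_sp", "n_tm", "n_both", "n_targeting",
                     "pct_sp", "pct_tm", "pct_targeting"],
        ),
        "targeting", config.seed,
    )

    # 3. UTR features (+ folding)
    transcripts = io.read_transcripts(config.fasta_path, config.ann_path)
    rule = utr.UORFRule(min_utr_length=config.min_utr_length)
    folder = None
    if config.fold_enabled:
        model = fold.EnergyModel(max_len=config.fold_max_len)
        folder = functools.partial(fold.mfe_fold, model=model)
    features = [utr.compute_features(t, rule, folder) for t in transcripts]
    io.write_tsv(
        out / "utr_features.tsv",
        pd.DataFrame(
            [
                (f.transcript_id, f.protein_id, f.length, f.gc_percent, f.delta_g,
                 f.uorf_count, f.excluded, f.reason)
                for f in features
            ],
            columns=["transcript_id", "protein_id", "length", "gc_percent",
                     "delta_g", "uorf_count", "excluded", "reason"],
        ),
        "utr-features", config.seed, min_utr_length=config.min_utr_length,
    )

    # 4. group comparison with proportional variant weighting
    two_group = {
        pid: ("regulated" if "regulated" in gs else "non-regulated")
        for pid, gs in groups.items()
    }
    profiles, dropped = groupstats.build_profiles(features, two_group)
    report["utr_comparison"] = {"n_proteins_dropped": len(dropped)}
    for feature_name, edges in (
        ("length", config.length_edges),
        ("uorf_count", None),
    ):
        comparison = groupstats.compare_groups(
            profiles, feature_name, edges=edges, method=config.stat_method,
            n_perm=config.n_perm, seed=config.seed,
        )
        report["utr_comparison"][feature_name] = {
            "chi2_stat": comparison.chi2_stat,
            "p_value": comparison.p_value,
            "method": comparison.method,
            "bins": comparison.bin_labels,
            "weighted_counts": {
                g: [round(v, 6) for v in row]
                for g, row in comparison.weighted_counts.iterrows()
            },
        }

    # 5. metabolite screen (optional)
    if config.peaks_path:
        peaks = io.read_peak_table(config.peaks_path, config.meta_path)
        normalized = metabolome.median_normalize(peaks)
        calls = metabolome.presence_calls(normalized)
        flux = metabolome.uptake_secretion(normalized)
        io.write_tsv(
            out / "metabolite_calls.tsv",
            pd.DataFrame(
                [
                    (c.metabolite, c.pattern, c.consistent_across_timepoints,
                     flux.loc[c.metabolite, "wt"], flux.loc[c.metabolite, "mutant"])
                    for c in calls
                ],
                columns=["metabolite", "presence_pattern", "consistent", "flux_wt", "flux_mutant"],
            ),
            "metabolome", config.seed,
        )
        report["metabolome"] = {
            "mutant_only": sorted(
                c.metabolite for c in calls
                if c.pattern == "mutant-only" and c.consistent_across_timepoints
            ),
            "wt_only": sorted(
                c.metabolite for c in calls
                if c.pattern == "wt-only" and c.consistent_across_timepoints
            ),
            "consumed_both_genotypes": sorted(
                flux.index[(flux["wt"] == "consumed") & (flux["mutant"] == "consumed")]
            ),
            "secreted_both_genotypes": sorted(
                flux.index[(flux["wt"] == "secreted") & (flux["mutant"] == "secreted")]
            ),
        }

    io.write_json(out / "report.json", report)
    return report
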