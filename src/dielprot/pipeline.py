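"""End-to-end orchestration: simulate → identify → quantify → pigments → report.

All stages are driven by one structured config and one seed; identical
(config, seed) pairs produce byte-identical output tables. Each stage logs
record counts in and out of every filter, and a run manifest records the
config snapshot, the seed and a SHA-256 digest of every file written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import icpl, identification, pigments, synthetic

__all__ = [
    "RunManifest",
    "ResultsBundle",
    "run_pipeline",
    "quantify_traces",
    "identify_psms",
    "summarize_fold_changes",
]

log = logging.getLogger("dielprot")


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str
    file_digests: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def record(self, path) -> None:
        path = Path(path)
        self.file_digests[path.name] = hashlib.sha256(
            path.read_bytes()).hexdigest()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps({
            "config": self.config, "seed": self.seed,
            "package_version": self.package_version,
            "file_digests": self.file_digests,
            "started": self.started, "finished": self.finished,
        }, indent=2, default=str))


@dataclass
class ResultsBundle:
    coverage: identification.CoverageReport
    fdr_by_method: dict
    differential: pd.DataFrame
    rejected: pd.DataFrame
    summaries: list
    pigment_results: Optional[pd.DataFrame]
    fold_change_bins: pd.DataFrame


def identify_psms(psms: pd.DataFrame, proteome: Mapping[str, str],
                  scan_range=(300.0, 1500.0), max_missed: int = 1,
                  fdr_formula: str = "decoy_over_target"):
    """Filter PSM tables per method, estimate FDR, build inventories + coverage."""
    inventories, fdrs, groups_by_method = {}, {}, {}
    for method, sub in psms.groupby("method"):
        records = [
            identification.PSM(
                peptide=r.peptide, protein_ids=frozenset([r.protein_id]),
                score=float(r.score), ion_score=float(r.ion_score),
                consecutive_ions=int(r.consecutive_ions),
                decoy=bool(r.decoy), method=method,
                replicate=int(r.replicate))
            for r in sub.itertuples()
        ]
        accepted = identification.filter_psms(records)
        log.info("identify[%s]: %d PSMs in, %d accepted", method,
                 len(records), len(accepted))
        fdrs[method] = identification.decoy_fdr(accepted, formula=fdr_formula)
        groups = identification.infer_proteins(
            accepted, proteome, scan_range=scan_range, max_missed=max_missed)
        groups_by_method[method] = groups
        inventories[method] = {g.representative for g in groups}
    coverage = identification.aggregate_methods(
        inventories, theoretical_size=len(proteome))
    return coverage, fdrs, groups_by_method


def quantify_traces(traces: pd.DataFrame, meta: pd.DataFrame,
                    up_threshold: float = icpl.UP_THRESHOLD,
                    down_threshold: float = icpl.DOWN_THRESHOLD,
                    alpha: float = 0.05, min_peptides: int = 2,
                    rule: str = "any_replicate"):
    """XIC trace tables → peptide ratios → protein records → retained table.

    Returns (differential table, rejected-peptide table, summaries).
    """
    meta_idx = meta.set_index(["peptide", "replicate"]).sort_index()
    if not meta_idx.index.is_unique:
        raise ValueError("pair metadata must be unique per (peptide, replicate)")
    ratios, rejects = [], []
    for (pep, rep), grp in traces.groupby(["peptide", "replicate"]):
        grp = grp.sort_values("rt")
        m = meta_idx.loc[(pep, rep)]
        light = icpl.XICTrace(grp.rt.to_numpy(), grp.intensity_light.to_numpy())
        heavy = icpl.XICTrace(grp.rt.to_numpy(), grp.intensity_heavy.to_numpy())
        pair = icpl.match_pair(light, heavy, peptide=pep,
                               protein_id=str(m["protein_id"]),
                               ion_score=float(m["ion_score"]),
                               replicate=int(rep))
        if isinstance(pair, icpl.PairRejection):
            rejects.append((pep, rep, pair.reason, pair.detail))
            continue
        ratio = icpl.peptide_ratio(pair)
        if isinstance(ratio, icpl.PairRejection):
            rejects.append((pep, rep, ratio.reason, ratio.detail))
            continue
        ratios.append(ratio)
    log.info("quantify: %d pairs quantified, %d rejected",
             len(ratios), len(rejects))
    rejected = pd.DataFrame(
        rejects, columns=["peptide", "replicate", "reason", "detail"])
    if not ratios:
        return pd.DataFrame(), rejected, []
    normalized = icpl.median_normalize(ratios)
    summaries = []
    by_protein: dict = {}
    for r in normalized:
        by_protein.setdefault(r.protein_id, {}).setdefault(
            r.replicate, []).append(r)
    n_reps = traces.replicate.nunique()
    for pid, reps in sorted(by_protein.items()):
        if len(reps) < n_reps:
            continue        # protein missing from a replicate: excluded
        records = [icpl.rollup_protein(v, protein_id=pid, replicate=k,
                                       alpha=alpha)
                   for k, v in sorted(reps.items())]
        summaries.append(icpl.combine_replicates(
            records, up_threshold=up_threshold, down_threshold=down_threshold))
    table = icpl.differential_filter(
        summaries, up_threshold=up_threshold, down_threshold=down_threshold,
        min_peptides=min_peptides, n_replicates=n_reps, rule=rule)
    return table, rejected, summaries


def summarize_fold_changes(summaries, bins_per_octave: int = 1) -> pd.DataFrame:
    """Histogram of combined ratios on a fixed geometric (octave) grid.

    Bin edges are powers of 2 (subdivided by ``bins_per_octave``); bins are
    lower-edge inclusive. Counts conserve the number of summaries.
    """
    if not len(summaries):
        raise ValueError("at least one summary is required")
    ratios = np.array([s.combined_ratio for s in summaries])
    logs = np.log2(ratios)
    step = 1.0 / bins_per_octave
    lo = math.floor(logs.min() / step) * step
    # extend one bin past the max so every bin is lower-edge inclusive
    hi = math.floor(logs.max() / step) * step + step
    edges = np.arange(lo, hi + step / 2, step)
    counts, _ = np.histogram(logs, bins=edges)
    return pd.DataFrame({
        "bin_low": 2.0 ** edges[:-1],
        "bin_high": 2.0 ** edges[1:],
        "count": counts,
    })


def run_pipeline(config: dict, outdir, seed: Optional[int] = None):
    """Execute every stage from a config mapping; write all artifacts.

    Config sections: ``simulate`` (SimConfig fields), ``quantify``
    (thresholds / alpha / min_peptides / rule), ``identify`` (scan_range,
    max_missed, fdr_formula), optional ``pigments`` (path to a readings
    TSV). Returns (ResultsBundle, RunManifest).
    """
    from importlib.metadata import version as _version

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = synthetic.SimConfig(**config.get("simulate", {}))
    if seed is not None:
        sim_cfg.seed = int(seed)
    manifest = RunManifest(config=dict(config), seed=sim_cfg.seed,
                           package_version=_version("dielprot"),
                           started=time.time())

    ds = synthetic.generate_dataset(sim_cfg)
    data_paths = synthetic.write_dataset(ds, outdir / "data")

    id_cfg = config.get("identify", {})
    proteome = dict(zip(ds.truth.proteins.protein_id,
                        ds.truth.proteins.sequence))
    coverage, fdrs, _ = identify_psms(
        ds.psms, proteome,
        scan_range=tuple(id_cfg.get("scan_range", sim_cfg.scan_range)),
        max_missed=id_cfg.get("max_missed", sim_cfg.max_missed_cleavages),
        fdr_formula=id_cfg.get("fdr_formula", "decoy_over_target"))

    q_cfg = config.get("quantify", {})
    table, rejected, summaries = quantify_traces(
        ds.xic, ds.xic_meta,
        up_threshold=q_cfg.get("up_threshold", icpl.UP_THRESHOLD),
        down_threshold=q_cfg.get("down_threshold", icpl.DOWN_THRESHOLD),
        alpha=q_cfg.get("alpha", 0.05),
        min_peptides=q_cfg.get("min_peptides", 2),
        rule=q_cfg.get("rule", "any_replicate"))

    pig_df = None
    pig_path = config.get("pigments", {}).get("readings")
    if pig_path:
        pig_df = pigments.process_readings(pd.read_csv(pig_path, sep="\t"))

    bins = (summarize_fold_changes(summaries)
            if summaries else pd.DataFrame(columns=["bin_low", "bin_high",
                                                    "count"]))

    # report stage: serialize every bundle field
    venn = pd.DataFrame(
        [("+".join(sorted(k)), v) for k, v in coverage.venn_regions.items()],
        columns=["region", "count"])
    artifacts = {
        "coverage.tsv": pd.DataFrame({
            "method": list(coverage.inventories),
            "n_proteins": [len(v) for v in coverage.inventories.values()],
            "exclusive": [coverage.exclusives[m] for m in coverage.inventories],
            "fdr_percent": [fdrs[m] for m in coverage.inventories],
        }),
        "venn_regions.tsv": venn,
        "differential.tsv": table,
        "rejected_peptides.tsv": rejected,
        "fold_change_bins.tsv": bins,
    }
    if pig_df is not None:
        artifacts["pigments.tsv"] = pig_df
    for name, df in artifacts.items():
        df.to_csv(outdir / name, sep="\t", index=False)
        manifest.record(outdir / name)
    for p in data_paths.values():
        manifest.record(p)
    manifest.finished = time.time()
    manifest.write(outdir / "manifest.json")

    bundle = ResultsBundle(
        coverage=coverage, fdr_by_method=fdrs, differential=table,
        rejected=rejected, summaries=summaries, pigment_results=pig_df,
        fold_change_bins=bins)
    return bundle, manifest
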