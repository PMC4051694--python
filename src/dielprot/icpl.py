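"""ICPL light/heavy quantification: XIC pairing, integration, ratio rollup.

Isotope-coded protein labeling (ICPL) tags lysines and peptide N-termini
with a light (12C) or heavy (13C) nicotinoyl group; relative abundance
between two states comes from the area ratio of the co-eluting labeled
peptide pair in the extracted ion chromatogram (XIC). Here the heavy label
marks the light-phase culture and the light label the dark-phase culture,
so the reported ratio is light-phase / dark-phase.

The pipeline is: pair light/heavy traces by Pearson correlation, integrate
each by Simpson's rule, form the heavy/light area ratio for peptides with
a sufficient ion score, median-normalize ratios within each run, average
per protein in natural-log space, and call a protein ratio significantly
different from unity when |x̄| > t·s/√N with t the two-sided 95% Student
critical value at N−1 degrees of freedom (x̄, s the mean and SD of the log
peptide ratios). Replicates are combined as the geometric mean.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate as _integrate
from scipy import stats as _stats

__all__ = [
    "XICTrace",
    "IsotopePair",
    "PairRejection",
    "PeptideRatio",
    "ProteinQuantRecord",
    "ReplicateSummary",
    "match_pair",
    "integrate_simpson",
    "peptide_ratio",
    "median_normalize",
    "rollup_protein",
    "combine_replicates",
    "differential_filter",
    "significant_from_stats",
    "load_reference_table",
    "summaries_from_table",
]

UP_THRESHOLD = 1.25
DOWN_THRESHOLD = 0.8
MIN_ION_SCORE = 30.0
CORRELATION_THRESHOLD = 0.8
MAX_XIC_WIDTH = 7        # scans, centered on the apex
XIC_THRESHOLD = 0.2      # fraction of apex intensity kept in the window


@dataclass(frozen=True)
class XICTrace:
    """One extracted ion chromatogram: intensity on a retention-time grid."""

    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        rt = np.asarray(self.rt, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "intensity", inten)
        if rt.shape != inten.shape or rt.ndim != 1:
            raise ValueError("rt and intensity must be 1-D arrays of equal length")
        if len(rt) > 1 and not np.all(np.diff(rt) > 0):
            raise ValueError("retention-time grid must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class IsotopePair:
    light: XICTrace
    heavy: XICTrace
    correlation: float
    area_light: float
    area_heavy: float
    peptide: str = ""
    protein_id: str = ""
    ion_score: float = 0.0
    replicate: int = 0


@dataclass(frozen=True)
class PairRejection:
    peptide: str
    reason: str
    detail: str = ""


@dataclass(frozen=True)
class PeptideRatio:
    raw_ratio: float          # area_heavy / area_light = light-phase / dark-phase
    normalized_ratio: Optional[float]
    peptide: str
    protein_id: str
    replicate: int
    ion_score: float = 0.0


@dataclass(frozen=True)
class ProteinQuantRecord:
    """Per-protein, per-replicate summary of log peptide ratios.

    ``log_mean`` (x̄) and ``log_sd`` (s, N−1 denominator) are on the natural
    log scale; ``ratio`` = exp(x̄) and ``sdgeo`` = exp(s) are their linear
    back-transforms. ``significant`` means |x̄| > t·s/√N at the two-sided
    95% level, which requires N ≥ 2.
    """

    protein_id: str
    n: int
    log_mean: float
    log_sd: float
    replicate: int
    significant: bool

    @property
    def ratio(self) -> float:
        return math.exp(self.log_mean)

    @property
    def sdgeo(self) -> float:
        return math.exp(self.log_sd)


@dataclass(frozen=True)
class ReplicateSummary:
    protein_id: str
    records: tuple                  # ProteinQuantRecord per replicate
    combined_ratio: float           # exp(mean of per-replicate x̄)
    combined_sdgeo: float           # exp(SD of per-replicate x̄)
    classification: str             # up / down / unchanged
    name: str = ""


def _overlap(light: XICTrace, heavy: XICTrace):
    common, il, ih = np.intersect1d(light.rt, heavy.rt, return_indices=True)
    return common, light.intensity[il], heavy.intensity[ih]


def match_pair(light: XICTrace, heavy: XICTrace,
               correlation_threshold: float = CORRELATION_THRESHOLD,
               max_width: int = MAX_XIC_WIDTH,
               xic_threshold: float = XIC_THRESHOLD,
               peptide: str = "", protein_id: str = "",
               ion_score: float = 0.0, replicate: int = 0):
    """Pair two traces if they co-elute (Pearson r ≥ threshold).

    The correlation is computed on the overlapping grid points. Accepted
    pairs are integrated over a window of at most ``max_width`` scans
    centered on the apex, with flanking points below ``xic_threshold`` of
    the apex intensity trimmed off. Returns an :class:`IsotopePair` or a
    :class:`PairRejection` with a reason code.
    """
    rt, y_l, y_h = _overlap(light, heavy)
    if len(rt) < 3:
        return PairRejection(peptide, "insufficient_overlap",
                             f"{len(rt)} overlapping points")
    if np.ptp(y_l) == 0 or np.ptp(y_h) == 0:
        return PairRejection(peptide, "undefined_correlation",
                             "constant trace has zero variance")
    corr = float(np.corrcoef(y_l, y_h)[0, 1])
    if not corr >= correlation_threshold:
        return PairRejection(peptide, "low_correlation", f"r={corr:.3f}")

    total = y_l + y_h
    apex = int(np.argmax(total))
    half = max_width // 2
    lo = max(0, apex - half)
    hi = min(len(rt), lo + max_width)
    lo = max(0, hi - max_width)

    def _window(y):
        # trim flanks of the apex window that fall below the XIC threshold
        w = np.arange(lo, hi)
        cut = xic_threshold * y[apex]
        a, b = 0, len(w)
        while a < b and y[w[a]] < cut:
            a += 1
        while b > a and y[w[b - 1]] < cut:
            b -= 1
        w = w[a:b]
        if len(w) < 3:          # too narrow to integrate; keep the full window
            w = np.arange(lo, hi)
        return XICTrace(rt[w], y[w])

    t_l, t_h = _window(y_l), _window(y_h)
    return IsotopePair(
        light=t_l, heavy=t_h, correlation=corr,
        area_light=integrate_simpson(t_l), area_heavy=integrate_simpson(t_h),
        peptide=peptide, protein_id=protein_id,
        ion_score=ion_score, replicate=replicate,
    )


def integrate_simpson(trace: XICTrace) -> float:
    """Composite Simpson integral of the trace.

    With an even number of points the final interval is handled by the
    trapezoid rule; non-uniform grids are handled by the per-interval-pair
    composite rule.
    """
    n = len(trace.rt)
    if n < 3:
        raise ValueError(f"Simpson integration needs >= 3 points, got {n}")
    if n % 2 == 1:
        return float(_integrate.simpson(trace.intensity, x=trace.rt))
    head = float(_integrate.simpson(trace.intensity[: n - 1], x=trace.rt[: n - 1]))
    tail = 0.5 * (trace.intensity[-1] + trace.intensity[-2]) * (
        trace.rt[-1] - trace.rt[-2]
    )
    return head + float(tail)


def peptide_ratio(pair: IsotopePair, min_ion_score: float = MIN_ION_SCORE):
    """Heavy/light area ratio for one accepted pair.

    Rejected when the ion score is not strictly above ``min_ion_score`` or
    either integrated area is zero.
    """
    if not pair.ion_score > min_ion_score:
        return PairRejection(pair.peptide, "low_ion_score",
                             f"ion score {pair.ion_score} <= {min_ion_score}")
    if pair.area_light == 0:
        return PairRejection(pair.peptide, "zero_light_area",
                             "division by zero light area")
    if pair.area_heavy == 0:
        return PairRejection(pair.peptide, "zero_heavy_area", "zero heavy area")
    return PeptideRatio(
        raw_ratio=pair.area_heavy / pair.area_light,
        normalized_ratio=None,
        peptide=pair.peptide,
        protein_id=pair.protein_id,
        replicate=pair.replicate,
        ion_score=pair.ion_score,
    )


def median_normalize(ratios: Sequence[PeptideRatio]) -> list:
    """Divide each raw ratio by the run (replicate) median of raw ratios.

    After normalization the within-run median is exactly 1 for odd run
    sizes and 1 by midpoint construction for even ones.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("at least one ratio is required")
    out = []
    for rep in sorted({r.replicate for r in ratios}):
        run = [r for r in ratios if r.replicate == rep]
        med = float(np.median([r.raw_ratio for r in run]))
        out.extend(replace(r, normalized_ratio=r.raw_ratio / med) for r in run)
    return out


def _critical_t(n: int, alpha: float = 0.05) -> float:
    return float(_stats.t.ppf(1.0 - alpha / 2.0, n - 1))


def rollup_protein(ratios: Sequence[PeptideRatio], protein_id: str = None,
                   replicate: int = None, alpha: float = 0.05) -> ProteinQuantRecord:
    """Average one protein's peptide ratios in natural-log space.

    x̄ and s are the mean and SD (N−1 denominator) of ln(normalized ratio);
    the protein is significantly different from unity when N ≥ 2 and
    |x̄| > t·s/√N with t the two-sided (1−alpha) Student critical value at
    N−1 degrees of freedom.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("cannot roll up an empty peptide-ratio list")
    if protein_id is None:
        protein_id = ratios[0].protein_id
    if replicate is None:
        replicate = ratios[0].replicate
    values = [
        r.normalized_ratio if r.normalized_ratio is not None else r.raw_ratio
        for r in ratios
    ]
    logs = np.log(values)
    n = len(logs)
    xbar = float(np.mean(logs))
    s = float(np.std(logs, ddof=1)) if n > 1 else 0.0
    significant = n >= 2 and abs(xbar) > _critical_t(n, alpha) * s / math.sqrt(n)
    return ProteinQuantRecord(
        protein_id=protein_id, n=n, log_mean=xbar, log_sd=s,
        replicate=replicate, significant=bool(significant),
    )


def significant_from_stats(ratio: float, sdgeo: float, n: int,
                           alpha: float = 0.05):
    """Significance-vs-unity test recomputed from summary statistics.

    Accepts the linear-scale (ratio, geometric SD, N) triple as printed in
    a results table and re-evaluates |ln ratio| > t·ln(sdgeo)/√N. Returns
    None when sdgeo is unavailable.
    """
    if n < 2:
        return False
    if sdgeo is None or (isinstance(sdgeo, float) and math.isnan(sdgeo)):
        return None
    return abs(math.log(ratio)) > _critical_t(n, alpha) * math.log(sdgeo) / math.sqrt(n)


def combine_replicates(records: Sequence[ProteinQuantRecord],
                       up_threshold: float = UP_THRESHOLD,
                       down_threshold: float = DOWN_THRESHOLD,
                       name: str = "") -> ReplicateSummary:
    """Combine per-replicate records for one protein in log space.

    Combined ratio = exp(mean of per-replicate x̄); combined geometric SD =
    exp(SD of per-replicate x̄). The classification is relative to the
    unchanged band (down_threshold, up_threshold).
    """
    records = tuple(sorted(records, key=lambda r: r.replicate))
    if not records:
        raise ValueError("no records to combine")
    ids = {r.protein_id for r in records}
    if len(ids) != 1:
        raise ValueError(f"records span multiple proteins: {sorted(ids)}")
    xbars = np.array([r.log_mean for r in records])
    combined = float(np.exp(xbars.mean()))
    sdgeo = float(np.exp(np.std(xbars, ddof=1))) if len(xbars) > 1 else 1.0
    if combined >= up_threshold:
        cls = "up"
    elif combined <= down_threshold:
        cls = "down"
    else:
        cls = "unchanged"
    return ReplicateSummary(
        protein_id=records[0].protein_id, records=records,
        combined_ratio=combined, combined_sdgeo=sdgeo,
        classification=cls, name=name,
    )


def differential_filter(summaries: Iterable[ReplicateSummary],
                        up_threshold: float = UP_THRESHOLD,
                        down_threshold: float = DOWN_THRESHOLD,
                        min_peptides: int = 2,
                        n_replicates: int = 2,
                        rule: str = "any_replicate") -> pd.DataFrame:
    """Retain differentially abundant proteins and label their direction.

    A protein must be quantified with at least ``min_peptides`` peptide
    ratios in every one of ``n_replicates`` replicates. Under the default
    ``any_replicate`` rule it is retained when at least one replicate is
    both significant and beyond a threshold (ratio ≥ up or ≤ down,
    inclusive). The ``strict_average`` variant instead requires the
    replicate-combined ratio to be beyond a threshold together with
    significance in at least one replicate. Direction is up when the
    combined ratio exceeds 1, down otherwise.
    """
    if not (0 < down_threshold < 1 < up_threshold):
        raise ValueError("thresholds must satisfy 0 < down < 1 < up")
    rows = []
    for s in summaries:
        if len(s.records) < n_replicates:
            continue
        if any(r.n < min_peptides for r in s.records):
            continue
        beyond = lambda r: r >= up_threshold or r <= down_threshold
        if rule == "any_replicate":
            retained = any(rec.significant and beyond(rec.ratio)
                           for rec in s.records)
        elif rule == "strict_average":
            retained = beyond(s.combined_ratio) and any(
                rec.significant for rec in s.records)
        else:
            raise ValueError(f"unknown retention rule {rule!r}")
        if not retained:
            continue
        row = {
            "accession": s.protein_id,
            "name": s.name,
            "combined_ratio": s.combined_ratio,
            "combined_sdgeo": s.combined_sdgeo,
            "direction": "up" if s.combined_ratio > 1 else "down",
        }
        for rec in s.records:
            k = rec.replicate
            row[f"ratio_rep{k}"] = rec.ratio
            row[f"sdgeo_rep{k}"] = rec.sdgeo
            row[f"n_rep{k}"] = rec.n
            row[f"sig_rep{k}"] = rec.significant
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Published reference ratio table


def load_reference_table() -> pd.DataFrame:
    """Published per-replicate ICPL ratio table of the A. platensis diel study.

    30 proteins with light-phase/dark-phase ratio, geometric SD, peptide
    count and printed significance flag for each of two biological
    replicates. Two geometric-SD cells were not printed and are NA.
    """
    ref = importlib.resources.files("dielprot") / "data" / "diel_differential_ratios.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def summaries_from_table(table: pd.DataFrame, replicates=(1, 2)) -> list:
    """Build :class:`ReplicateSummary` objects from a printed ratio table.

    Each replicate's significance flag is taken from the table (the printed
    marking) rather than recomputed; x̄ = ln ratio and s = ln SDgeo recover
    the log-space statistics from the printed linear values.
    """
    summaries = []
    for _, row in table.iterrows():
        records = []
        for k in replicates:
            sdgeo = row[f"sdgeo_rep{k}"]
            log_sd = math.log(sdgeo) if pd.notna(sdgeo) else float("nan")
            records.append(ProteinQuantRecord(
                protein_id=row["accession"],
                n=int(row[f"n_rep{k}"]),
                log_mean=math.log(row[f"ratio_rep{k}"]),
                log_sd=log_sd,
                replicate=k,
                significant=bool(row[f"sig_rep{k}"]),
            ))
        summaries.append(combine_replicates(records, name=row.get("name", "")))
    return summaries
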