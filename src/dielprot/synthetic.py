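"""Synthetic ground-truth data for the shotgun ICPL pipeline.

Generates, from a single seeded random stream: a random proteome with
lognormal copy numbers and assigned light/dark fold changes; per-method PSM
tables whose detection structure induces the Venn overlaps seen in
multi-fractionation experiments (abundant proteins are detected by more
methods); decoy PSMs at a configurable rate with scores from the null
component; and co-eluting Gaussian light/heavy XIC pairs whose area ratio
is the protein's true ratio perturbed by lognormal peptide noise. Every
downstream stage of the package can therefore be exercised, and its
recovery measured against the truth, without any external data.

The defaults describe the emulated study conditions: two biological
replicates, a 300–1500 m/z scan window, four fractionation workflows, and
noise magnitudes chosen to be realistic for ion-trap ICPL data (the
geometric SDs they induce sit in the range typically reported). They are
documented in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .identification import STANDARD_RESIDUES, digest

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_proteome",
    "simulate_psm_tables",
    "simulate_xic_pairs",
    "generate_dataset",
    "write_dataset",
]

RESIDUES = np.array(sorted(STANDARD_RESIDUES))
LABEL_MASS_DELTA = 6.0201   # Da per ICPL label site (6 x 13C-12C)

DEFAULT_METHODS = {
    "IEF": 0.30,
    "SDS-PAGE": 0.30,
    "2D-LC": 0.60,
    "3D-LC": 0.50,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    ``fold_change_spec`` is a list of (fraction_of_proteins, true
    light/dark ratio) pairs whose fractions sum to 1;
    ``peptide_ratio_noise_sigma`` is the SD of natural-log peptide ratios
    around the protein's true log ratio; ``method_detection_probs`` gives
    each fractionation workflow's per-peptide detection probability for a
    protein of median abundance rank.
    """

    n_proteins: int = 200
    mean_protein_length: int = 300
    abundance_mu: float = 8.0          # lognormal log-mean of copy number
    abundance_sigma: float = 1.5       # lognormal log-SD of copy number
    fold_change_spec: Sequence = ((0.8, 1.0), (0.1, 2.0), (0.1, 0.5))
    n_replicates: int = 2
    peptide_ratio_noise_sigma: float = 0.25
    method_detection_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METHODS))
    quant_detection_prob: float = 0.6  # per-peptide prob in the ICPL runs
    decoy_psm_rate: float = 0.01
    scan_range: tuple = (300.0, 1500.0)
    max_missed_cleavages: int = 1
    rt_spacing: float = 1.0            # retention-time grid step (scans)
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if self.abundance_sigma <= 0 or self.mean_protein_length < 10:
            raise ConfigError("invalid abundance or length parameters")
        if self.peptide_ratio_noise_sigma <= 0:
            raise ConfigError("peptide_ratio_noise_sigma must be > 0")
        fracs = [f for f, _ in self.fold_change_spec]
        if any(f < 0 for f in fracs) or not math.isclose(sum(fracs), 1.0,
                                                         abs_tol=1e-9):
            raise ConfigError("fold_change_spec fractions must sum to 1")
        if any(r <= 0 for _, r in self.fold_change_spec):
            raise ConfigError("true ratios must be > 0")
        probs = list(self.method_detection_probs.values())
        probs.append(self.quant_detection_prob)
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("detection probabilities must lie in [0, 1]")
        if not 0 <= self.decoy_psm_rate < 1:
            raise ConfigError("decoy_psm_rate must lie in [0, 1)")
        if not self.scan_range[0] < self.scan_range[1]:
            raise ConfigError("scan range low must be < high")


@dataclass
class GroundTruth:
    """Simulated truth: per-protein abundance/ratio and the peptide table.

    ``proteins`` columns: protein_id, sequence, abundance, true_ratio,
    detectability (logistic score of abundance rank in (0, 1)).
    ``peptides`` columns: protein_id, peptide, missed_cleavages, mono_mass,
    label_sites (lysines + 1 N-terminus), detectability.
    """

    proteins: pd.DataFrame
    peptides: pd.DataFrame


@dataclass
class SyntheticDataset:
    config: SimConfig
    truth: GroundTruth
    psms: pd.DataFrame            # per-method identification PSM tables
    xic: pd.DataFrame             # long-format paired traces, all replicates
    xic_meta: pd.DataFrame        # one row per (peptide, replicate) pair


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(RESIDUES, size=length))


def _assign_fold_changes(rng, n: int, spec) -> np.ndarray:
    # largest-remainder apportionment of proteins to fold-change classes,
    # then a random permutation so classes are not abundance-correlated
    fracs = np.array([f for f, _ in spec], dtype=float)
    ratios = [r for _, r in spec]
    exact = fracs * n
    counts = np.floor(exact).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:rem]] += 1
    values = np.repeat(ratios, counts)
    return values[rng.permutation(n)]


def _detectability(abundance: np.ndarray) -> np.ndarray:
    """Logistic score of the abundance quantile rank, in (0, 1).

    More abundant proteins get scores near 1 and are detected by more
    methods, reproducing the dominance of abundant proteins in real
    inventories.
    """
    n = len(abundance)
    rank = np.argsort(np.argsort(abundance))
    q = (rank + 1) / (n + 1)
    return 1.0 / (1.0 + np.exp(-4.0 * (q - 0.5)))


def generate_proteome(config: SimConfig) -> GroundTruth:
    """Draw sequences, abundances and true fold changes for the proteome."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    lengths = np.maximum(
        30, rng.normal(config.mean_protein_length,
                       0.3 * config.mean_protein_length, size=n).astype(int))
    sequences = [_random_sequence(rng, L) for L in lengths]
    abundance = rng.lognormal(config.abundance_mu, config.abundance_sigma, size=n)
    true_ratio = _assign_fold_changes(rng, n, config.fold_change_spec)
    detect = _detectability(abundance)
    proteins = pd.DataFrame({
        "protein_id": [f"SYN_{i:05d}" for i in range(n)],
        "sequence": sequences,
        "abundance": abundance,
        "true_ratio": true_ratio,
        "detectability": detect,
    })
    pep_rows = []
    for pid, seq, d in zip(proteins.protein_id, sequences, detect):
        for pep in digest(seq, config.max_missed_cleavages):
            pep_rows.append((pid, pep.sequence, pep.missed_cleavages,
                             pep.mono_mass, pep.sequence.count("K") + 1, d))
    peptides = pd.DataFrame(
        pep_rows, columns=["protein_id", "peptide", "missed_cleavages",
                           "mono_mass", "label_sites", "detectability"])
    # repeated identical tryptic products of one protein are one peptide species
    peptides = peptides.drop_duplicates(
        subset=["protein_id", "peptide"], ignore_index=True)
    return GroundTruth(proteins=proteins, peptides=peptides)


def _detection_prob(method_prob: float, detectability: np.ndarray) -> np.ndarray:
    """Per-peptide detection probability for one method.

    p = m**(1/s): a protein with detectability score s near 1 keeps nearly
    the method's nominal probability m, a low-abundance one decays fast;
    m = 1 stays certain for every protein.
    """
    if method_prob >= 1.0:
        return np.ones_like(detectability)
    if method_prob <= 0.0:
        return np.zeros_like(detectability)
    return method_prob ** (1.0 / detectability)


def simulate_psm_tables(truth: GroundTruth, config: SimConfig,
                        rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """One identification PSM table per fractionation method.

    Target scores come from the high-score (correct-match) component,
    decoys from the low-score null component; decoys are injected so their
    fraction among all PSMs converges to ``decoy_psm_rate``.
    """
    config.validate()
    if not config.method_detection_probs:
        raise ConfigError("method_detection_probs must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    peps = truth.peptides
    rows = []
    r = config.decoy_psm_rate
    for method, prob in sorted(config.method_detection_probs.items()):
        p = _detection_prob(prob, peps.detectability.to_numpy())
        detected = rng.random(len(peps)) < p
        sub = peps[detected]
        n_t = len(sub)
        scores = np.clip(rng.normal(85.0, 20.0, n_t), 1.0, None)
        ion_scores = np.clip(rng.normal(45.0, 12.0, n_t), 1.0, None)
        cons = rng.poisson(8.0, n_t)
        for (pep, pid), sc, isc, ci in zip(
                zip(sub.peptide, sub.protein_id), scores, ion_scores, cons):
            rows.append((pep, pid, sc, isc, ci, False, method, 0))
        n_d = rng.binomial(n_t, r / (1.0 - r)) if (r > 0 and n_t > 0) else 0
        if n_d:
            picks = rng.integers(0, len(peps), n_d)
            d_scores = np.clip(rng.normal(20.0, 8.0, n_d), 0.1, None)
            d_ion = np.clip(rng.normal(10.0, 5.0, n_d), 0.0, None)
            d_cons = rng.poisson(1.0, n_d)
            for j, (k, sc, isc, ci) in enumerate(
                    zip(picks, d_scores, d_ion, d_cons)):
                rows.append((peps.peptide.iloc[k][::-1],
                             f"DECOY_{method}_{j:05d}", sc, isc, ci,
                             True, method, 0))
    return pd.DataFrame(rows, columns=[
        "peptide", "protein_id", "score", "ion_score", "consecutive_ions",
        "decoy", "method", "replicate"])


def simulate_xic_pairs(truth: GroundTruth, config: SimConfig, replicate: int,
                       rng: Optional[np.random.Generator] = None,
                       n_points: int = 21, peak_width: float = 2.0):
    """Co-eluting Gaussian light/heavy trace pairs for one replicate.

    Both traces of a pair share center and width on the replicate's
    retention-time grid; the heavy:light area ratio equals the protein's
    true ratio times exp(Normal(0, sigma)). The heavy peptide mass is the
    light mass plus 6.0201 Da per label site (metadata only).

    Returns (traces, meta): ``traces`` holds the sampled grids, ``meta``
    one row per pair with areas implied by the amplitudes and the noisy
    ratio actually applied.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 100 + replicate)
    peps = truth.peptides.merge(
        truth.proteins[["protein_id", "abundance", "true_ratio"]],
        on="protein_id")
    # a sequence shared by several proteins is ambiguous for quantification;
    # keep one pair per distinct peptide sequence
    peps = peps.drop_duplicates(subset="peptide", keep="first")
    p = _detection_prob(config.quant_detection_prob,
                        peps.detectability.to_numpy())
    sel = peps[rng.random(len(peps)) < p]
    trace_rows, meta_rows = [], []
    sigma = config.peptide_ratio_noise_sigma
    for _, row in sel.iterrows():
        center = rng.uniform(50.0, 950.0)
        noisy_ratio = row.true_ratio * math.exp(rng.normal(0.0, sigma))
        amp_light = row.abundance * rng.lognormal(0.0, 0.1)
        ion_score = float(np.clip(rng.normal(45.0, 10.0), 1.0, None))
        half = (n_points // 2) * config.rt_spacing
        rt = np.arange(center - half, center + half + config.rt_spacing / 2,
                       config.rt_spacing)
        shape = np.exp(-((rt - center) ** 2) / (2.0 * peak_width ** 2))
        light = amp_light * shape
        heavy = amp_light * noisy_ratio * shape
        for t, yl, yh in zip(rt, light, heavy):
            trace_rows.append((row.peptide, replicate, t, yl, yh))
        meta_rows.append((
            row.peptide, row.protein_id, replicate, ion_score,
            row.true_ratio, noisy_ratio, row.mono_mass,
            row.mono_mass + LABEL_MASS_DELTA * row.label_sites,
            int(row.label_sites)))
    traces = pd.DataFrame(trace_rows, columns=[
        "peptide", "replicate", "rt", "intensity_light", "intensity_heavy"])
    meta = pd.DataFrame(meta_rows, columns=[
        "peptide", "protein_id", "replicate", "ion_score", "true_ratio",
        "noisy_ratio", "mass_light", "mass_heavy", "label_sites"])
    return traces, meta


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Full synthetic study: proteome, PSM tables, XIC pairs for every replicate."""
    truth = generate_proteome(config)
    psms = simulate_psm_tables(truth, config)
    all_traces, all_meta = [], []
    for rep in range(1, config.n_replicates + 1):
        traces, meta = simulate_xic_pairs(truth, config, rep)
        all_traces.append(traces)
        all_meta.append(meta)
    return SyntheticDataset(
        config=config, truth=truth, psms=psms,
        xic=pd.concat(all_traces, ignore_index=True),
        xic_meta=pd.concat(all_meta, ignore_index=True))


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Serialize a dataset: FASTA proteome, PSM/XIC/truth TSVs."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": outdir / "proteome.fasta",
        "psms": outdir / "psms.tsv",
        "xic": outdir / "xic_traces.tsv",
        "xic_meta": outdir / "xic_pairs.tsv",
        "truth": outdir / "ground_truth.tsv",
    }
    records = [
        SeqRecord(Seq(row.sequence), id=row.protein_id, description="")
        for row in ds.truth.proteins.itertuples()
    ]
    SeqIO.write(records, paths["proteome"], "fasta")
    ds.psms.to_csv(paths["psms"], sep="\t", index=False)
    ds.xic.to_csv(paths["xic"], sep="\t", index=False)
    ds.xic_meta.to_csv(paths["xic_meta"], sep="\t", index=False)
    ds.truth.proteins.drop(columns=["sequence"]).to_csv(
        paths["truth"], sep="\t", index=False)
    return paths
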