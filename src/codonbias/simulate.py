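"""Synthetic CDS catalogs and count matrices with planted codon-usage bias.

The generator emulates the statistical structure a tissue-specific codon
usage analysis sees: a set of coding sequences whose synonymous-codon choice
follows a per-tissue preference vector, and a bulk RNA-seq count matrix in
which each tissue over-expresses its own gene module.  A planted enrichment
multiplies the focus codons (default ACT/ACC, the threonine codons decoded
by tRNA-Thr-AGT) within their synonymous family and renormalises the family,
so amino-acid composition is held fixed and the planted signal is purely
synonymous — the same footprint a tRNA-modification effect would leave.

Every draw is governed by ``SimSpec.seed``; catalog, counts and everything
downstream are byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import CODON_INDEX, SENSE_CODONS, SYNONYMOUS_FAMILIES, GENETIC_CODE
from .expression import ExpressionMatrix
from .sequence_io import CodingSequence, TranscriptCatalog, write_cds_fasta

# Amino-acid composition of a typical eukaryotic proteome (mole fractions).
DEFAULT_AMINO_ACID_FREQS: dict[str, float] = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.053, "C": 0.018,
    "Q": 0.040, "E": 0.062, "G": 0.066, "H": 0.026, "I": 0.053,
    "L": 0.091, "K": 0.058, "M": 0.023, "F": 0.040, "P": 0.051,
    "S": 0.081, "T": 0.057, "W": 0.013, "Y": 0.032, "V": 0.065,
}

# Baseline wobble-position skew: C/G-ending codons preferred, as in the
# GC-rich fly coding genome.
_WOBBLE_WEIGHT = {"A": 0.8, "C": 1.4, "G": 1.4, "T": 0.8}

# Baseline threonine-family preference.  ACT/ACC are deliberately the minor
# codons so a planted ACT/ACC boost is a genuine minor-to-major synonymous
# shift rather than a reshuffle among already-dominant codons.
_THR_BASELINE = {"ACT": 0.18, "ACC": 0.22, "ACA": 0.35, "ACG": 0.25}


def default_synonymous_preferences() -> dict[str, dict[str, float]]:
    """Baseline synonymous-codon preference per amino acid (sums to 1)."""
    prefs: dict[str, dict[str, float]] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        if aa == "T":
            prefs[aa] = dict(_THR_BASELINE)
            continue
        weights = np.array([_WOBBLE_WEIGHT[c[2]] for c in family], dtype=float)
        weights /= weights.sum()
        prefs[aa] = {c: float(w) for c, w in zip(family, weights)}
    return prefs


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic dataset.

    ``enrichment`` maps a tissue name to a multiplicative boost f >= 1
    applied to the focus codons within their synonymous families for genes
    homed in that tissue.  ``background_fraction`` of genes belong to no
    tissue module (baseline preferences, baseline expression everywhere, in
    no DE list); the rest are split round-robin across tissues.
    ``dispersion`` is the negative-binomial size parameter r
    (variance = mean + mean^2 / r; r -> inf recovers Poisson noise).
    """

    n_genes: int = 500
    cds_length_codons: tuple[int, int] = (300, 900)  # body codons, uniform
    tissues: tuple[str, ...] = ("wing_disc", "fat_body", "muscle")
    background_fraction: float = 0.4
    amino_acid_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AMINO_ACID_FREQS)
    )
    synonymous_prefs: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_synonymous_preferences
    )
    enrichment: Mapping[str, float] = field(default_factory=dict)
    focus_set: tuple[str, ...] = ("ACT", "ACC")
    depth: float = 1000.0
    dispersion: float = 10.0
    home_expression_boost: float = 8.0
    column_scale_factors: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.cds_length_codons
        if lo < 1 or hi < lo:
            raise ValueError("cds_length_codons must be (min >= 1, max >= min)")
        if not self.tissues:
            raise ValueError("at least one tissue is required")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in [0, 1)")
        for t, f in self.enrichment.items():
            if t not in self.tissues:
                raise ValueError(f"enrichment names unknown tissue {t!r}")
            if f < 1.0:
                raise ValueError("enrichment factors must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.home_expression_boost < 1:
            raise ValueError("home_expression_boost must be >= 1")
        if self.column_scale_factors is not None:
            sf = np.asarray(self.column_scale_factors, dtype=float)
            if sf.shape != (len(self.tissues),) or (sf <= 0).any():
                raise ValueError("column_scale_factors must be positive, one per tissue")
        for aa, vec in self.synonymous_prefs.items():
            total = sum(vec.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"synonymous preferences for {aa} sum to {total}, not 1")

    # -- derived structure -------------------------------------------------

    @property
    def n_background(self) -> int:
        return int(round(self.background_fraction * self.n_genes))

    def home_tissues(self) -> tuple[str | None, ...]:
        """Deterministic home-tissue assignment: background genes first,
        then round-robin across tissues."""
        n_bg = self.n_background
        homes: list[str | None] = [None] * n_bg
        for i in range(self.n_genes - n_bg):
            homes.append(self.tissues[i % len(self.tissues)])
        return tuple(homes)

    def gene_ids(self) -> tuple[str, ...]:
        width = max(4, len(str(self.n_genes - 1)))
        return tuple(f"g{i:0{width}d}" for i in range(self.n_genes))

    def codon_probs(self, tissue: str | None = None) -> np.ndarray:
        """64-slot codon probability vector for genes homed in ``tissue``
        (None = baseline/background; stop slots are zero).

        The tissue's enrichment factor multiplies the focus codons and the
        affected synonymous families are renormalised, keeping each family's
        total (the amino-acid composition) fixed.
        """
        aa_total = sum(self.amino_acid_freqs.values())
        probs = np.zeros(64, dtype=float)
        for aa, family in SYNONYMOUS_FAMILIES.items():
            aa_freq = self.amino_acid_freqs[aa] / aa_total
            for codon in family:
                probs[CODON_INDEX[codon]] = aa_freq * self.synonymous_prefs[aa][codon]
        f = self.enrichment.get(tissue, 1.0) if tissue is not None else 1.0
        if f != 1.0:
            for aa in {GENETIC_CODE[c] for c in self.focus_set}:
                idx = [CODON_INDEX[c] for c in SYNONYMOUS_FAMILIES[aa]]
                family_mass = probs[idx].sum()
                boosted = probs[idx] * np.array(
                    [f if c in self.focus_set else 1.0 for c in SYNONYMOUS_FAMILIES[aa]]
                )
                probs[idx] = boosted * (family_mass / boosted.sum())
        return probs


@dataclass(frozen=True)
class SimTruth:
    """Ground truth accompanying a generated catalog."""

    home_tissue: dict[str, str | None]
    true_freqs: dict[str, np.ndarray]  # gene -> assigned 64-slot probability
    gene_lists: dict[str, tuple[str, ...]]  # tissue -> its module ("DE") genes


def _rng(spec: SimSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(stream,)))


def generate_catalog(spec: SimSpec) -> tuple[TranscriptCatalog, SimTruth]:
    """Draw a CDS catalog: each gene is ATG + i.i.d. sense codons from its
    home tissue's preference vector + TAA."""
    rng = _rng(spec, 0)
    homes = spec.home_tissues()
    gene_ids = spec.gene_ids()
    lo, hi = spec.cds_length_codons
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)

    sense_idx = np.array([CODON_INDEX[c] for c in SENSE_CODONS])
    codon_arr = np.array(SENSE_CODONS)
    prob_cache: dict[str | None, np.ndarray] = {}
    records: list[CodingSequence] = []
    truth_freqs: dict[str, np.ndarray] = {}
    for gid, home, n_codons in zip(gene_ids, homes, lengths):
        if home not in prob_cache:
            prob_cache[home] = spec.codon_probs(home)
        p64 = prob_cache[home]
        p = p64[sense_idx]
        draws = rng.choice(len(sense_idx), size=int(n_codons), p=p)
        body = "".join(codon_arr[draws])
        records.append(CodingSequence(f"tr_{gid}", gid, "ATG" + body + "TAA"))
        truth_freqs[gid] = p64
    gene_lists = {
        t: tuple(g for g, h in zip(gene_ids, homes) if h == t) for t in spec.tissues
    }
    truth = SimTruth(dict(zip(gene_ids, homes)), truth_freqs, gene_lists)
    return TranscriptCatalog(tuple(records)), truth


def generate_counts(catalog: TranscriptCatalog, spec: SimSpec) -> ExpressionMatrix:
    """Negative-binomial count matrix (genes x tissues).

    Gene g in tissue t has mean ``depth * boost`` if t is g's home tissue and
    ``depth`` otherwise, times the planted column scale factor when given.
    """
    rng = _rng(spec, 1)
    homes = spec.home_tissues()
    gene_ids = [rec.gene_id for rec in catalog]
    if len(gene_ids) != spec.n_genes:
        raise ValueError("catalog does not match spec (gene count differs)")
    boost = spec.home_expression_boost
    scale = (
        np.asarray(spec.column_scale_factors, dtype=float)
        if spec.column_scale_factors is not None
        else np.ones(len(spec.tissues))
    )
    mean = np.empty((spec.n_genes, len(spec.tissues)))
    for j, t in enumerate(spec.tissues):
        mean[:, j] = spec.depth * np.where([h == t for h in homes], boost, 1.0) * scale[j]
    r = spec.dispersion
    if np.isinf(r):
        counts = rng.poisson(mean)
    else:
        counts = rng.negative_binomial(r, r / (r + mean))
    table = pd.DataFrame(counts.astype(float), index=gene_ids, columns=list(spec.tissues))
    return ExpressionMatrix(table)


# ---------------------------------------------------------------------------
# Analytic expectation
# ---------------------------------------------------------------------------


def _expected_profiles(spec: SimSpec, mode: str) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Expected max-normalised tissue usage vectors and genome vector.

    ``mode="gene_list"`` mirrors running the pipeline with each tissue's own
    module gene list; ``mode="all"`` mirrors summing over all matched genes
    with expression weights.  Length distributions are identical across
    modules, so expected lengths cancel from the genome aggregate.
    """
    homes = spec.home_tissues()
    pool_sizes: dict[str | None, int] = {}
    for h in homes:
        pool_sizes[h] = pool_sizes.get(h, 0) + 1
    probs = {h: spec.codon_probs(h) for h in pool_sizes}

    genome = np.zeros(64)
    for h, n in pool_sizes.items():
        genome += n * probs[h]
    g_scaled = genome / genome.max()

    tissue_vectors: dict[str, np.ndarray] = {}
    for t in spec.tissues:
        if mode == "gene_list":
            if pool_sizes.get(t, 0) == 0:
                raise ValueError(f"tissue {t!r} has no module genes under this spec")
            u = probs[t].copy()
        elif mode == "all":
            u = np.zeros(64)
            for h, n in pool_sizes.items():
                w = spec.home_expression_boost if h == t else 1.0
                u += n * w * probs[h]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        tissue_vectors[t] = u / u.max()
    return tissue_vectors, g_scaled


def expected_bias(spec: SimSpec, mode: str = "gene_list") -> dict[str, dict[str, float]]:
    """Closed-form expectation of the pipeline's focus-codon bias ratios.

    Returns ``{tissue: {codon: expected ratio}}`` for the focus codons,
    under the same mixture of preference vectors and expression weights the
    generator plants.  Monotone non-decreasing in each tissue's enrichment
    factor.
    """
    tissue_vectors, genome = _expected_profiles(spec, mode)
    out: dict[str, dict[str, float]] = {}
    for t, u in tissue_vectors.items():
        out[t] = {}
        for c in spec.focus_set:
            i = CODON_INDEX[c]
            out[t][c] = float(u[i] / genome[i]) if genome[i] > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------


def write_simulation(spec: SimSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + counts TSV + truth JSON for a spec; returns the paths.

    The truth JSON records the home-tissue assignment, per-tissue gene lists,
    the planted enrichment and the analytic expected focus ratios.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog, truth = generate_catalog(spec)
    matrix = generate_counts(catalog, spec)
    fasta = out_dir / "cds.fa"
    counts = out_dir / "counts.tsv"
    truth_path = out_dir / "truth.json"
    write_cds_fasta(catalog, fasta)
    matrix.data.to_csv(counts, sep="\t", index_label="gene_id", float_format="%.12g")
    payload = {
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "tissues": list(spec.tissues),
        "enrichment": dict(spec.enrichment),
        "focus_set": list(spec.focus_set),
        "home_tissue": truth.home_tissue,
        "gene_lists": {t: list(g) for t, g in truth.gene_lists.items()},
        "expected_focus_bias": expected_bias(spec),
    }
    truth_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    for t, genes in truth.gene_lists.items():
        (out_dir / f"{t}_genes.txt").write_text("\n".join(genes) + "\n")
    return {"fasta": fasta, "counts": counts, "truth": truth_path}
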