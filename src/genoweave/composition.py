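"""Coding-region nucleotide-composition statistics.

GC3 is the fraction of codons whose third base is G or C; the CG3 skew,
(C3-G3)/(C3+G3), measures the cytosine/guanine asymmetry at third positions
that tracks transcription and methylation; the CpG "genomic signature"
rho_CG = f_CG/(f_C*f_G) measures dinucleotide CG depletion or enrichment.
The module also ranks genes into GC3-rich/-poor deciles, traces positional
composition gradients along open reading frames, fits three generative
nucleotide models of coding sequence (multinomial, position-specific
multinomial, and a first-order codon-position-periodic Markov chain), and
runs the per-category goodness-of-fit test used to compare functional
annotations of the rich and poor classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
MODEL_KINDS = ("multinomial", "position_specific", "markov3")


@dataclass(frozen=True)
class CompositionProfile:
    """Third-position composition of one coding sequence."""

    gene: str
    L: int                      # CDS length in nt as supplied
    n_codons: int               # codons counted (complete, N-free)
    c3: int
    g3: int
    gc: float
    gc3: float
    cg3_skew: float | None      # None when C3+G3 == 0
    third_bases: tuple[str | None, ...]  # None marks an uncounted codon


@dataclass(frozen=True)
class SignatureValue:
    rho_cg: float | None        # None when f_C * f_G == 0
    f_cg: float
    f_c: float
    f_g: float


@dataclass(frozen=True)
class GradientCurve:
    codon_index: tuple[int, ...]      # 1-based codon positions
    mean_value: tuple[float, ...]
    n_genes: tuple[int, ...]


@dataclass(frozen=True)
class NucleotideModel:
    """A generative model of coding sequence over A/C/G/T.

    ``probs`` is (4,) for the multinomial, (3,4) per codon position for the
    position-specific multinomial, and (3,4,4) for the first-order periodic
    Markov chain, where ``probs[pos, prev, cur]`` conditions the base at
    codon position ``pos`` on the immediately preceding base.
    """

    kind: str
    probs: np.ndarray
    training_codons: int

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-12) or (self.probs < 0).any():
            raise ValueError("probability vectors must be non-negative and sum to 1")


# ---------------------------------------------------------------------------


def codon_composition(cds: str, gene: str = "") -> CompositionProfile:
    """Per-gene GC, GC3, CG3 skew and per-codon third bases.

    A trailing partial codon and any codon containing a non-ACGT base are
    excluded from every count (and marked ``None`` in ``third_bases``).
    """
    if len(cds) < 3:
        raise ValueError(f"gene {gene!r}: CDS shorter than one codon")
    if len(cds) % 3:
        logger.debug("gene %r: trailing partial codon excluded", gene)
    thirds: list[str | None] = []
    c3 = g3 = 0
    gc_bases = total_bases = 0
    n_valid = 0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if any(b not in _BASE_INDEX for b in codon):
            thirds.append(None)
            continue
        n_valid += 1
        thirds.append(codon[2])
        c3 += codon[2] == "C"
        g3 += codon[2] == "G"
        gc_bases += sum(b in "GC" for b in codon)
        total_bases += 3
    if n_valid == 0:
        raise ValueError(f"gene {gene!r}: no complete N-free codon")
    gc3 = (c3 + g3) / n_valid
    skew = (c3 - g3) / (c3 + g3) if (c3 + g3) > 0 else None
    return CompositionProfile(
        gene=gene, L=len(cds), n_codons=n_valid, c3=c3, g3=g3,
        gc=gc_bases / total_bases, gc3=gc3, cg3_skew=skew,
        third_bases=tuple(thirds),
    )


def genomic_signature(seq: str) -> SignatureValue:
    """CpG relative abundance rho_CG = f_CG / (f_C * f_G).

    Dinucleotide frequency is over overlapping pairs; mononucleotide
    frequencies are over all bases.
    """
    if len(seq) < 2:
        raise ValueError("sequence shorter than one dinucleotide")
    n = len(seq)
    f_c = seq.count("C") / n
    f_g = seq.count("G") / n
    f_cg = sum(1 for i in range(n - 1) if seq[i : i + 2] == "CG") / (n - 1)
    rho = f_cg / (f_c * f_g) if f_c * f_g > 0 else None
    return SignatureValue(rho_cg=rho, f_cg=f_cg, f_c=f_c, f_g=f_g)


# ---------------------------------------------------------------------------


def classify_deciles(
    profiles: Sequence[CompositionProfile],
    fraction: float = 0.10,
    rounding: str = "half-up",
) -> tuple[list[CompositionProfile], list[CompositionProfile], float, float]:
    """Split genes into GC3-rich (top decile) and GC3-poor (bottom decile).

    Set sizes are ``round(fraction * N)`` half-up by default (floor/ceil via
    ``rounding``); ties at the boundary break by gene id so the sizes are
    exact.  Returns (rich, poor, rich_threshold, poor_threshold) where the
    thresholds are the minimum GC3 of the rich set and the maximum GC3 of
    the poor set.
    """
    n = len(profiles)
    if n < 10:
        raise ValueError("need at least 10 genes to form deciles")
    if rounding == "half-up":
        size = int(np.floor(fraction * n + 0.5))
    elif rounding == "floor":
        size = int(np.floor(fraction * n))
    elif rounding == "ceil":
        size = int(np.ceil(fraction * n))
    else:
        raise ValueError("rounding must be half-up, floor or ceil")
    rich = sorted(profiles, key=lambda p: (-p.gc3, p.gene))[:size]
    poor = sorted(profiles, key=lambda p: (p.gc3, p.gene))[:size]
    rich_threshold = min(p.gc3 for p in rich)
    poor_threshold = max(p.gc3 for p in poor)
    return rich, poor, rich_threshold, poor_threshold


def positional_gradients(
    profiles: Sequence[CompositionProfile],
    max_codon: int | None = None,
) -> tuple[GradientCurve, GradientCurve]:
    """Mean GC3 and CG3-skew at each codon position along the ORF.

    At codon index k (1-based) the GC3 curve averages the indicator
    {third base is G or C} over genes with at least k counted codons; the
    skew curve averages +1 for C and -1 for G over genes whose k-th third
    base is C or G.  No padding: short genes simply stop contributing.
    """
    if not profiles:
        raise ValueError("no profiles")
    longest = max(len(p.third_bases) for p in profiles)
    K = longest if max_codon is None else min(max_codon, longest)
    idx, gc_mean, gc_n, sk_mean, sk_n = [], [], [], [], []
    for k in range(K):
        gc_vals = []
        sk_vals = []
        for p in profiles:
            if k >= len(p.third_bases) or p.third_bases[k] is None:
                continue
            b = p.third_bases[k]
            gc_vals.append(1.0 if b in "GC" else 0.0)
            if b == "C":
                sk_vals.append(1.0)
            elif b == "G":
                sk_vals.append(-1.0)
        idx.append(k + 1)
        gc_mean.append(float(np.mean(gc_vals)) if gc_vals else float("nan"))
        gc_n.append(len(gc_vals))
        sk_mean.append(float(np.mean(sk_vals)) if sk_vals else float("nan"))
        sk_n.append(len(sk_vals))
    gc_curve = GradientCurve(tuple(idx), tuple(gc_mean), tuple(gc_n))
    skew_curve = GradientCurve(tuple(idx), tuple(sk_mean), tuple(sk_n))
    return gc_curve, skew_curve


# ---------------------------------------------------------------------------


def _codon_aligned_indices(cds: str) -> np.ndarray | None:
    usable = len(cds) - len(cds) % 3
    if usable < 3:
        return None
    try:
        return np.array([_BASE_INDEX[b] for b in cds[:usable]])
    except KeyError:
        # sequences with ambiguity codes: mask N positions as -1
        return np.array([_BASE_INDEX.get(b, -1) for b in cds[:usable]])


def fit_nucleotide_models(cds_set: Iterable[str], kind: str) -> NucleotideModel:
    """Maximum-likelihood fit of one of the three coding-sequence models.

    ``markov3`` conditions each base on the preceding base with one 4x4
    transition matrix per codon position of the *current* base; transitions
    across codon boundaries use the previous codon's third base.  Unseen
    contexts get a uniform row (logged).
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    base_counts = np.zeros(4)
    pos_counts = np.zeros((3, 4))
    trans_counts = np.zeros((3, 4, 4))
    n_codons = 0
    for cds in cds_set:
        arr = _codon_aligned_indices(cds)
        if arr is None:
            continue
        n_codons += len(arr) // 3
        pos = np.arange(len(arr)) % 3
        valid = arr >= 0
        np.add.at(base_counts, arr[valid], 1)
        np.add.at(pos_counts, (pos[valid], arr[valid]), 1)
        ok = valid[1:] & valid[:-1]
        np.add.at(trans_counts, (pos[1:][ok], arr[:-1][ok], arr[1:][ok]), 1)
    if n_codons == 0:
        raise ValueError("no codons to train on")
    if kind == "multinomial":
        probs = base_counts / base_counts.sum()
    elif kind == "position_specific":
        probs = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    else:
        row_sums = trans_counts.sum(axis=2, keepdims=True)
        unseen = row_sums[..., 0] == 0
        if unseen.any():
            logger.debug("markov3: %d unseen contexts set to uniform",
                         int(unseen.sum()))
        probs = np.where(row_sums > 0, trans_counts / np.maximum(row_sums, 1),
                         0.25)
    return NucleotideModel(kind=kind, probs=probs, training_codons=n_codons)


def sample_cds(model: NucleotideModel, n_codons: int,
               rng: np.random.Generator) -> str:
    """Draw a coding sequence of ``n_codons`` codons from a fitted model.

    For ``markov3`` the first base is drawn uniformly (it carries no
    transition information).
    """
    L = 3 * n_codons
    if model.kind == "multinomial":
        draws = rng.choice(4, size=L, p=model.probs)
    elif model.kind == "position_specific":
        draws = np.empty(L, dtype=int)
        for pos in range(3):
            draws[pos::3] = rng.choice(4, size=n_codons, p=model.probs[pos])
    else:
        draws = np.empty(L, dtype=int)
        draws[0] = rng.integers(0, 4)
        unif = rng.random(L)
        cum = np.cumsum(model.probs, axis=-1)
        for i in range(1, L):
            draws[i] = np.searchsorted(cum[i % 3, draws[i - 1]], unif[i])
    return "".join(_BASES[i] for i in draws)


def log_likelihood(model: NucleotideModel, cds_set: Iterable[str]) -> float:
    """Total log-likelihood of coding sequences under a fitted model.

    For ``markov3`` the initial base of each sequence is scored uniformly.
    """
    total = 0.0
    with np.errstate(divide="ignore"):
        logp = np.log(model.probs)
    for cds in cds_set:
        arr = _codon_aligned_indices(cds)
        if arr is None:
            continue
        pos = np.arange(len(arr)) % 3
        valid = arr >= 0
        if model.kind == "multinomial":
            total += float(logp[arr[valid]].sum())
        elif model.kind == "position_specific":
            total += float(logp[pos[valid], arr[valid]].sum())
        else:
            total += float(np.log(0.25))
            ok = valid[1:] & valid[:-1]
            total += float(logp[pos[1:][ok], arr[:-1][ok], arr[1:][ok]].sum())
    return total


# ---------------------------------------------------------------------------


def enrichment_test(
    category_counts_rich: Mapping[str, int],
    category_counts_poor: Mapping[str, int],
    background: Mapping[str, int],
):
    """Per-category goodness-of-fit of rich/poor counts against background.

    Under the null, genes fall into a functional category at the same rate
    in the rich set, the poor set and the genome-wide background, so the
    expected cell counts are |rich| * b_i/B and |poor| * b_i/B.  Each
    category is tested with a chi-squared statistic over its (rich, poor)
    cells at df = cells - 1.  Returns a pandas DataFrame with columns
    category, chi2, df, p_value.
    """
    import pandas as pd

    cats = list(category_counts_rich)
    if set(cats) != set(category_counts_poor) or not set(cats) <= set(background):
        raise ValueError("rich/poor/background categories must align")
    n_rich = sum(category_counts_rich.values())
    n_poor = sum(category_counts_poor.values())
    b_total = sum(background[c] for c in cats)
    rows = []
    for c in cats:
        share = background[c] / b_total
        expected = np.array([n_rich * share, n_poor * share], dtype=float)
        if (expected == 0).any():
            raise ValueError(f"category {c!r}: expected count of zero")
        observed = np.array(
            [category_counts_rich[c], category_counts_poor[c]], dtype=float
        )
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        df = observed.size - 1
        p = float(stats.chi2.sf(chi2, df))
        rows.append({"category": c, "chi2": chi2, "df": df, "p_value": p})
    return pd.DataFrame(rows)
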