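"""PWM promoter scanning with matrix-similarity scoring.

A position weight matrix is scored against every window of a promoter,
on both strands, with the information-weighted matrix-similarity score

    mss(w) = sum_i C_i f(i, w_i) / sum_i C_i max_b f(i, b)

where C_i = (100/ln 4) (sum_b f ln f + ln 4) is the per-position
information weight (0 for a uniform position, 100 for a fully
conserved one).  The score is 1 exactly when every window base is its
position's most frequent base; hits are called at mss >= 0.80.

Enrichment of motif presence in a gene set is assessed by comparing
the observed statistics (number of genes with >= 1 promoter hit; mean
hits per promoter) against random same-size gene draws.  A one-tailed
Wilcoxon rank-sum test asks whether genes with more promoter sites
show larger absolute expression fold changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from scipy.stats import mannwhitneyu

from .coexpression import PermutationResult
from .expression import InvalidInputError

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def information_vector(freqs: np.ndarray) -> np.ndarray:
    """Per-position information weight C_i on a 0..100 scale.

    C_i = (100/ln 4) * (sum_b f ln f + ln 4), with 0*ln 0 = 0.
    """
    f = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(f > 0, f * np.log(f), 0.0)
    return (100.0 / math.log(4)) * (term.sum(axis=1) + math.log(4))


@dataclass
class PWM:
    """Base-frequency matrix of a binding motif (columns A, C, G, T)."""

    freqs: np.ndarray
    name: str = "pwm"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise InvalidInputError("PWM must be width x 4")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidInputError("PWM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    @property
    def info(self) -> np.ndarray:
        return information_vector(self.freqs)

    @classmethod
    def from_counts(cls, counts: np.ndarray, name: str = "pwm",
                    pseudocount: float = 0.0) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(c / c.sum(axis=1, keepdims=True), name=name)


@dataclass
class MotifHit:
    """A PWM match within one promoter (promoter-relative coordinates)."""

    gene: str
    offset: int  # 0-based start of the matched window on the forward strand
    strand: str
    score: float


def matrix_similarity(pwm: PWM, window: str, pseudocount: float = 0.0) -> float:
    """Information-weighted similarity of one window to the PWM, in [0,1].

    Windows containing ambiguous bases score 0 (no hit).
    """
    if len(window) != pwm.width:
        raise InvalidInputError("window length must equal PWM width")
    f = pwm.freqs
    if pseudocount:
        f = (f + pseudocount) / (1 + 4 * pseudocount)
    ci = pwm.info
    denom = float((ci * f.max(axis=1)).sum())
    num = 0.0
    for i, base in enumerate(window.upper()):
        j = _CODE.get(base)
        if j is None:
            return 0.0
        num += ci[i] * f[i, j]
    return num / denom


def _encode(seq: str) -> np.ndarray:
    """Sequence to integer codes; non-ACGT bases become 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _CODE.items():
        codes[arr == ord(b)] = i
    return codes


def _score_forward(pwm: PWM, codes: np.ndarray, pseudocount: float) -> np.ndarray:
    """Matrix-similarity score of every window start on one strand."""
    w = pwm.width
    n = codes.size - w + 1
    if n <= 0:
        return np.empty(0)
    f = pwm.freqs
    if pseudocount:
        f = (f + pseudocount) / (1 + 4 * pseudocount)
    ci = pwm.info
    denom = (ci * f.max(axis=1)).sum()
    fx = np.hstack([f, np.zeros((w, 1))])  # ambiguous base contributes 0
    num = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i in range(w):
        cw = codes[i : i + n]
        num += ci[i] * fx[i, cw]
        valid &= cw < 4
    scores = num / denom
    scores[~valid] = 0.0
    return scores


def scan_promoter(
    pwm: PWM, promoter: str, threshold: float = 0.8,
    gene: str = "", pseudocount: float = 0.0,
) -> list[MotifHit]:
    """All PWM hits in one promoter, both strands, at mss >= threshold.

    Offsets are forward-strand 0-based window starts on either strand;
    a reverse-complement-palindromic consensus therefore yields two
    hits at one locus, one per strand.
    """
    codes = _encode(promoter)
    w = pwm.width
    if codes.size < w:
        return []
    hits: list[MotifHit] = []
    fwd = _score_forward(pwm, codes, pseudocount)
    for off in np.nonzero(fwd >= threshold)[0]:
        hits.append(MotifHit(gene, int(off), "+", float(fwd[off])))
    rc = _encode(reverse_complement(promoter))
    rev = _score_forward(pwm, rc, pseudocount)
    L = codes.size
    for off in np.nonzero(rev >= threshold)[0]:
        # position j on the reverse complement covers forward bases
        # [L - w - j, L - j)
        hits.append(MotifHit(gene, int(L - w - off), "-", float(rev[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(
    pwm: PWM, promoters: dict[str, str], threshold: float = 0.8,
    pseudocount: float = 0.0,
) -> dict[str, list[MotifHit]]:
    return {
        g: scan_promoter(pwm, seq, threshold, gene=g, pseudocount=pseudocount)
        for g, seq in promoters.items()
    }


def count_exact_matches(seq: str, motif: str) -> int:
    """Overlapping occurrences of an exact motif string on one strand."""
    codes = _encode(seq)
    target = _encode(motif)
    w = target.size
    if codes.size < w:
        return 0
    ok = np.ones(codes.size - w + 1, dtype=bool)
    for i in range(w):
        ok &= codes[i : codes.size - w + 1 + i] == target[i]
    return int(ok.sum())


def permutation_motif_enrichment(
    geneset,
    promoters: dict[str, str],
    pwm: PWM,
    threshold: float = 0.8,
    n_perm: int = 1000,
    seed: int = 0,
    hit_counts: dict[str, int] | None = None,
) -> tuple[PermutationResult, PermutationResult]:
    """Permutation enrichment of motif presence in a gene set.

    Two statistics against random same-size draws from the promoter
    universe: (1) the number of query genes with at least one promoter
    hit, and (2) the mean number of hits per query promoter.  Returns
    a PermutationResult for each.  ``hit_counts`` may carry
    precomputed per-gene hit counts to skip rescanning.
    """
    geneset = list(geneset)
    universe = sorted(promoters)
    if not universe:
        raise InvalidInputError("empty promoter universe")
    missing = set(geneset) - set(universe)
    if missing:
        raise InvalidInputError(f"genes without promoter: {sorted(missing)[:5]}")
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    if hit_counts is None:
        hit_counts = {
            g: len(scan_promoter(pwm, promoters[g], threshold)) for g in universe
        }
    counts = np.array([hit_counts[g] for g in universe], dtype=float)
    idx_of = {g: i for i, g in enumerate(universe)}
    q = np.array([idx_of[g] for g in geneset])
    obs_genes = float(np.sum(counts[q] > 0))
    obs_freq = float(counts[q].mean())
    rng = np.random.default_rng(seed)
    null_genes = np.empty(n_perm)
    null_freq = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(len(universe), size=len(geneset), replace=False)
        null_genes[i] = np.sum(counts[pick] > 0)
        null_freq[i] = counts[pick].mean()
    return (
        PermutationResult(obs_genes, null_genes, n_perm, seed),
        PermutationResult(obs_freq, null_freq, n_perm, seed),
    )


def wilcoxon_by_motif_count(
    fc: dict | pd.Series,
    counts: dict | pd.Series,
    bins: list[tuple[int, float]],
    exact_max: int = 12,
) -> pd.DataFrame:
    """One-tailed rank-sum comparisons of |log2fc| across site-count bins.

    ``bins`` is a list of inclusive (lo, hi) site-count ranges ordered
    from fewest to most sites.  Each adjacent pair is compared under
    H1 "the higher-count bin has larger |log2fc|": exact enumeration
    when both groups have <= ``exact_max`` untied observations, a
    tie-corrected normal approximation otherwise.  Empty bins are
    skipped with a warning.
    """
    fc = pd.Series(fc, dtype=float)
    counts = pd.Series(counts)
    groups = []
    for lo, hi in bins:
        members = counts.index[(counts >= lo) & (counts <= hi)]
        vals = fc.loc[[g for g in members if g in fc.index]].to_numpy()
        if vals.size == 0:
            warnings.warn(f"empty motif-count bin [{lo},{hi}]", stacklevel=2)
        groups.append(((lo, hi), vals))
    rows = []
    for ((lo1, hi1), g1), ((lo2, hi2), g2) in zip(groups, groups[1:]):
        if g1.size == 0 or g2.size == 0:
            continue
        rows.append(
            {
                "bin_low": f"[{lo1},{hi1}]",
                "bin_high": f"[{lo2},{hi2}]",
                "n_low": g1.size,
                "n_high": g2.size,
                "p": rank_sum_greater(g2, g1, exact_max=exact_max),
            }
        )
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "n_low", "n_high", "p"])


def rank_sum_greater(x: np.ndarray, y: np.ndarray, exact_max: int = 12) -> float:
    """One-tailed Wilcoxon rank-sum p for H1: x stochastically > y.

    Exact enumeration of rank assignments when both samples are small
    and untied; otherwise the normal approximation with tie-corrected
    variance (and continuity correction).  Fully tied data gives 0.5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("empty group in rank-sum test")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        return 0.5  # all observations identical: z = 0
    if not ties and x.size <= exact_max and y.size <= exact_max:
        return float(mannwhitneyu(x, y, alternative="greater", method="exact").pvalue)
    return float(
        mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Promoter FASTA: record id = gene id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_transfac(path) -> PWM:
    """Read the first matrix from a TRANSFAC-format file as a PWM.

    Counts (or frequencies) are normalized per row.
    """
    with open(path) as fh:
        records = bio_motifs.parse(fh, "transfac")
    if not records:
        raise InvalidInputError(f"no TRANSFAC matrix in {path}")
    mot = records[0]
    counts = np.array([[mot.counts[b][i] for b in BASES]
                       for i in range(mot.length)], dtype=float)
    name = mot.get("ID") or mot.get("AC") or "pwm"
    return PWM.from_counts(counts, name=name)


def load_default_pwm() -> PWM:
    """The bundled synthetic RAX-like PWM (consensus core TAATTA).

    A stand-in constructed from the published consensus: the true
    MatInspector RAX matrix is proprietary.  Strongly conserved TAATTA
    core with weakly informative flanks.
    """
    ref = resources.files("rxnet") / "data" / "rax_synthetic.transfac"
    with resources.as_file(ref) as path:
        return read_transfac(path)


def write_hits_bed(hits: list[MotifHit], path: str, width: int) -> None:
    """Hits as BED-like TSV, promoter-relative 0-based half-open."""
    with open(path, "w") as fh:
        fh.write("gene\tstart\tend\tstrand\tscore\n")
        for h in hits:
            fh.write(
                f"{h.gene}\t{h.offset}\t{h.offset + width}\t{h.strand}\t"
                f"{h.score:.4f}\n"
            )
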