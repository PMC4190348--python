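"""Two-condition differential expression under a Poisson count model.

Replicates are pooled (summed) per condition.  Under the null
hypothesis of equal per-base transcription rates, the pooled count of
condition A conditioned on the total K = k1 + k2 is
Binomial(K, N1/(N1+N2)) where N1, N2 are the library sizes; the
two-sided p-value sums the binomial point probabilities that do not
exceed the probability of the observed count (minimum-likelihood
method).  This is an exact conditional equivalent of testing equality
of two Poisson rates.

Selection follows the mutant-screen convention: log2 fold change is
log2(sibling/mutant), so positive values mean lower expression in the
mutant; genes pass with fold change >= 1.5 (or <= 2/3) and
Bonferroni-corrected p < 0.001.

Note the pooled Poisson test is anticonservative on overdispersed
(biologically replicated) data: with no replicate-level variance
component, library-scale tests treat all variation as shot noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom

from .expression import ExpressionMatrix, InvalidInputError

#: numerical slack when comparing point probabilities (float round-off)
_REL_TOL = 1e-12


def log2_fold_change(rpkm_sib: float, rpkm_mut: float, floor: float = 1e-9) -> float:
    """log2(sibling / mutant), with both RPKMs floored to avoid infinities."""
    if rpkm_sib < 0 or rpkm_mut < 0:
        raise InvalidInputError("negative RPKM")
    return float(np.log2(max(rpkm_sib, floor) / max(rpkm_mut, floor)))


def poisson_de_test(k1: int, k2: int, N1: float, N2: float) -> float:
    """Exact conditional two-sided p-value for equal Poisson rates.

    Given K = k1 + k2, under H0 k1 ~ Binomial(K, N1/(N1+N2)); the
    two-sided p sums all point probabilities <= that of the observed
    k1.  K = 0 carries no information and returns 1.
    """
    if k1 < 0 or k2 < 0:
        raise InvalidInputError("negative counts")
    if N1 <= 0 or N2 <= 0:
        raise InvalidInputError("library sizes must be positive")
    K = int(k1) + int(k2)
    if K == 0:
        return 1.0
    p0 = N1 / (N1 + N2)
    pmf = binom.pmf(np.arange(K + 1), K, p0)
    obs = pmf[int(k1)]
    return float(min(1.0, pmf[pmf <= obs * (1 + _REL_TOL)].sum()))


def poisson_de_pvalues(
    k1: np.ndarray, k2: np.ndarray, N1: float, N2: float
) -> np.ndarray:
    """Vectorized `poisson_de_test` over per-gene pooled counts."""
    k1 = np.asarray(k1, dtype=np.int64)
    k2 = np.asarray(k2, dtype=np.int64)
    if (k1 < 0).any() or (k2 < 0).any():
        raise InvalidInputError("negative counts")
    if N1 <= 0 or N2 <= 0:
        raise InvalidInputError("library sizes must be positive")
    p0 = N1 / (N1 + N2)
    out = np.ones(k1.shape, dtype=float)
    for i, (a, b) in enumerate(zip(k1, k2)):
        K = int(a + b)
        if K == 0:
            continue
        pmf = binom.pmf(np.arange(K + 1), K, p0)
        obs = pmf[int(a)]
        out[i] = min(1.0, pmf[pmf <= obs * (1 + _REL_TOL)].sum())
    return out


def bonferroni(p_values) -> np.ndarray:
    """q_i = min(1, m * p_i) with m the number of tested genes."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise InvalidInputError("p-values outside [0,1]")
    return np.minimum(1.0, p * p.size)


def select_de(
    results: pd.DataFrame, alpha: float = 0.001, fc: float = 1.5
) -> pd.DataFrame:
    """Assign DE status from fold change and corrected p.

    down_in_mutant: FC >= fc (log2fc >= log2 fc) and q < alpha;
    up_in_mutant:   FC <= 1/fc and q < alpha; otherwise ns.  The fold
    change gates are inclusive, the significance gate strict.
    """
    res = results.copy()
    lo, hi = -np.log2(fc), np.log2(fc)
    sig = res["q"] < alpha
    res["status"] = "ns"
    res.loc[sig & (res["log2fc"] >= hi), "status"] = "down_in_mutant"
    res.loc[sig & (res["log2fc"] <= lo), "status"] = "up_in_mutant"
    return res


def run_de(
    counts: ExpressionMatrix,
    lengths: pd.Series | dict,
    condition_a: str = "sibling",
    condition_b: str = "mutant",
    alpha: float = 0.001,
    fc: float = 1.5,
    rpkm_floor: float = 1e-9,
) -> pd.DataFrame:
    """Full DE stage on a filtered count matrix with sample metadata.

    Returns a table with columns gene, rpkm_sib, rpkm_mut, log2fc,
    p_raw, q, status (sibling = ``condition_a``).
    """
    counts.require_units("counts")
    if counts.sample_meta is None:
        raise InvalidInputError("sample metadata required for DE")
    cond = counts.sample_meta["condition"]
    cols_a = [s for s in counts.sample_ids if cond.loc[s] == condition_a]
    cols_b = [s for s in counts.sample_ids if cond.loc[s] == condition_b]
    if not cols_a or not cols_b:
        raise InvalidInputError(
            f"conditions {condition_a!r}/{condition_b!r} not found in sample sheet"
        )
    pooled_a = counts.values[cols_a].sum(axis=1)
    pooled_b = counts.values[cols_b].sum(axis=1)
    N1, N2 = float(pooled_a.sum()), float(pooled_b.sum())
    lengths = pd.Series(lengths, dtype=float).loc[counts.gene_ids]
    rpkm_a = pooled_a / (lengths / 1e3) / (N1 / 1e6)
    rpkm_b = pooled_b / (lengths / 1e3) / (N2 / 1e6)
    p_raw = poisson_de_pvalues(pooled_a.to_numpy(), pooled_b.to_numpy(), N1, N2)
    q = bonferroni(p_raw)
    log2fc = np.log2(
        np.maximum(rpkm_a.to_numpy(), rpkm_floor)
        / np.maximum(rpkm_b.to_numpy(), rpkm_floor)
    )
    res = pd.DataFrame(
        {
            "gene": counts.gene_ids,
            "rpkm_sib": rpkm_a.to_numpy(),
            "rpkm_mut": rpkm_b.to_numpy(),
            "log2fc": log2fc,
            "p_raw": p_raw,
            "q": q,
        }
    ).set_index("gene", drop=False)
    return select_de(res, alpha=alpha, fc=fc)


def write_de_table(res: pd.DataFrame, path: str) -> None:
    """Write the DE table in the report layout (gene, RPKMs, FC, Q, status)."""
    out = res[["gene", "rpkm_sib", "rpkm_mut", "log2fc", "p_raw", "q", "status"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
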