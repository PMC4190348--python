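"""Expression matrices: RPKM, filtering, normalization, z-scores.

The container is a genes × samples table with a unit tag; operations
check the tag so the pipeline order (counts → RPKM → quantile →
replicate averaging → log2 → z-score) cannot be violated silently.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

UNITS = ("counts", "rpkm", "log2rpkm", "zscore")


class UnitError(ValueError):
    """An operation was applied to a matrix in the wrong units."""


class InvalidInputError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with sample metadata.

    ``sample_meta`` (optional) is indexed by sample id with columns
    ``condition``, ``replicate`` and ``stage``.
    """

    values: pd.DataFrame
    units: str = "counts"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise UnitError(f"unknown units {self.units!r}")
        if self.values.isna().any().any():
            raise InvalidInputError("expression matrix contains missing cells")
        if self.units in {"counts", "rpkm"} and (self.values.values < 0).any():
            raise InvalidInputError(f"negative values in a {self.units} matrix")
        if self.sample_meta is not None:
            missing = set(self.values.columns) - set(self.sample_meta.index)
            if missing:
                raise InvalidInputError(f"samples without metadata: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def require_units(self, *allowed: str) -> None:
        if self.units not in allowed:
            raise UnitError(
                f"operation requires units in {allowed}, matrix has {self.units!r}"
            )

    def _with(self, values: pd.DataFrame, units: str | None = None,
              sample_meta: pd.DataFrame | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            units=units if units is not None else self.units,
            sample_meta=sample_meta if sample_meta is not None else self.sample_meta,
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @staticmethod
    def from_tsv(path: str, units: str = "counts",
                 sample_meta: pd.DataFrame | None = None) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return ExpressionMatrix(values=df, units=units, sample_meta=sample_meta)


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Read a sample sheet TSV (sample, condition, replicate, stage)."""
    meta = pd.read_csv(path, sep="\t", dtype=str).set_index("sample")
    return meta


def write_sample_sheet(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_low_counts(counts: ExpressionMatrix, min_total: int = 10) -> ExpressionMatrix:
    """Keep genes with strictly more than ``min_total`` reads summed over samples."""
    counts.require_units("counts")
    keep = counts.values.sum(axis=1) > min_total
    logger.info("low-count filter: %d/%d genes retained", int(keep.sum()), len(keep))
    return counts._with(counts.values.loc[keep])


def compute_rpkm(
    counts: ExpressionMatrix,
    lengths: pd.Series | dict,
    library_sizes: pd.Series | dict | None = None,
) -> ExpressionMatrix:
    """Reads per kilobase of gene model per million library reads.

    RPKM = count / ((length/1e3) * (library/1e6)).  The library size
    defaults to the column sum of the count table; an override table
    (e.g. total aligned reads) may be supplied.
    """
    counts.require_units("counts")
    lengths = pd.Series(lengths, dtype=float)
    missing = set(counts.gene_ids) - set(lengths.index)
    if missing:
        raise InvalidInputError(f"genes without length: {sorted(missing)[:5]} ...")
    lens = lengths.loc[counts.gene_ids]
    if (lens <= 0).any():
        raise InvalidInputError("non-positive gene length")
    if library_sizes is None:
        lib = counts.values.sum(axis=0).astype(float)
    else:
        lib = pd.Series(library_sizes, dtype=float).loc[counts.sample_ids]
    if (lib <= 0).any():
        raise InvalidInputError("zero or negative library size")
    rpkm = counts.values.div(lens / 1e3, axis=0).div(lib / 1e6, axis=1)
    return counts._with(rpkm, units="rpkm")


def classify_tier(rpkm: float) -> str:
    """Expression tier: high (RPKM >= 5), moderate (0.5 <= RPKM < 5), low."""
    if rpkm < 0:
        raise InvalidInputError("negative RPKM")
    if rpkm >= 5:
        return "high"
    if rpkm >= 0.5:
        return "moderate"
    return "low"


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the shared mean empirical distribution.

    Each column's sorted values are replaced by the across-column mean
    of sorted values; values tied within a column receive the mean of
    the target values at their tied ranks.
    """
    if m.values.shape[1] < 2:
        raise InvalidInputError("quantile normalization needs >= 2 samples")
    X = m.values.to_numpy(dtype=float)
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        assigned = target[rankdata(col, method="ordinal") - 1]
        # average the targets over tied ranks
        s = pd.Series(assigned).groupby(col).transform("mean")
        out[:, j] = s.to_numpy()
    return m._with(pd.DataFrame(out, index=m.values.index, columns=m.values.columns))


def average_replicates(
    m: ExpressionMatrix, grouping: dict | pd.Series | None = None
) -> ExpressionMatrix:
    """Average replicate columns within each developmental stage.

    ``grouping`` maps sample id → stage; if omitted it is read from the
    sample metadata.  Stage order follows first appearance among the
    matrix columns.
    """
    if grouping is None:
        if m.sample_meta is None or "stage" not in m.sample_meta.columns:
            raise InvalidInputError("no grouping given and no stage metadata")
        grouping = m.sample_meta["stage"]
    grouping = pd.Series(grouping)
    missing = set(m.sample_ids) - set(grouping.index)
    if missing:
        raise InvalidInputError(f"samples without stage: {sorted(missing)}")
    stages: list[str] = []
    members: dict[str, list[str]] = {}
    for s in m.sample_ids:
        st = grouping.loc[s]
        if st not in members:
            stages.append(st)
            members[st] = []
        members[st].append(s)
    for st in stages:
        if not members[st]:
            raise InvalidInputError(f"empty stage group {st!r}")
    out = pd.DataFrame(
        {st: m.values[members[st]].mean(axis=1) for st in stages},
        index=m.values.index,
    )
    meta = pd.DataFrame(
        {"condition": "pooled", "replicate": "1", "stage": stages},
        index=pd.Index(stages, name="sample"),
    )
    return m._with(out, sample_meta=meta)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    m.require_units("rpkm")
    if pseudocount < 0 and (m.values.values <= -pseudocount).any():
        raise InvalidInputError("negative pseudocount with non-positive values")
    if pseudocount == 0 and (m.values.values == 0).any():
        raise InvalidInputError("pseudocount 0 with zero values")
    return m._with(np.log2(m.values + pseudocount), units="log2rpkm")


def zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene z-scores: subtract the row mean, divide by the sample sd (n-1).

    Constant rows become all-zero (with a warning) rather than NaN.
    """
    if m.values.shape[1] < 2:
        raise InvalidInputError("z-scores need >= 2 columns")
    X = m.values.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant gene row(s) mapped to all-zero z-scores",
            stacklevel=2,
        )
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    Z[const, :] = 0.0
    return m._with(
        pd.DataFrame(Z, index=m.values.index, columns=m.values.columns),
        units="zscore",
    )
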