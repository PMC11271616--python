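"""Compositional preparation of taxa count tables.

Counts arrive as a samples x taxa table of non-negative integers. Because
amplicon counts are compositional (the library size is an artefact of
sequencing depth, not of the ecosystem), downstream models operate on
centred log-ratio (CLR) values: the log of each taxon's pseudo-counted
abundance relative to the geometric mean of all taxa in the same sample.
The CLR is computed over *all* taxa; the prevalence filter only restricts
which taxa are carried into the association screens.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "validate_count_table",
    "library_sizes",
    "clr_transform",
    "filter_by_prevalence",
    "zscore",
    "presence_flag",
    "bristol_group",
]


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a samples x taxa count table and return it unchanged.

    Raises ``ValueError`` on duplicate sample/taxon identifiers, negative
    or non-integer entries.
    """
    if counts.index.has_duplicates:
        raise ValueError("duplicate sample ids in count table")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate taxon ids in count table")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count table must be numeric")
    if (values < 0).any():
        raise ValueError("count table contains negative entries")
    if not np.allclose(values, np.round(values)):
        raise ValueError("count table contains non-integer entries")
    return counts


def library_sizes(counts: pd.DataFrame) -> pd.Series:
    """Total sequence count per sample (exact row sum of raw counts)."""
    return counts.sum(axis=1).rename("library_size")


def clr_transform(counts: pd.DataFrame, pseudo: float = 0.5) -> pd.DataFrame:
    """Centred log-ratio transform with a pseudo-count.

    ``clr[s, t] = ln(count[s, t] + pseudo) - mean_t ln(count[s, t] + pseudo)``

    The pseudo-count (default 0.5) avoids taking the log of zero counts.
    Every row of the result sums to zero (up to floating point).

    Parameters
    ----------
    counts:
        Samples x taxa non-negative integer table.
    pseudo:
        Positive offset added to every count before the log.
    """
    validate_count_table(counts)
    if counts.shape[1] < 2:
        raise ValueError(
            "CLR is undefined for a single-taxon table (only determined up to a constant)"
        )
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    logged = np.log(counts.to_numpy(dtype=float) + pseudo)
    clr = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def filter_by_prevalence(
    counts: pd.DataFrame,
    min_rel: float = 1e-4,
    min_frac_samples: float = 0.10,
) -> list:
    """Taxa passing a minimum relative-abundance prevalence rule.

    A taxon is retained iff its relative abundance (raw count over library
    size, no pseudo-count) is at least ``min_rel`` in at least
    ``ceil(min_frac_samples * n_samples)`` samples. Defaults correspond to
    0.01% relative abundance in at least 10% of samples.

    Returns the retained taxon ids in table column order.
    """
    validate_count_table(counts)
    libs = library_sizes(counts)
    if (libs <= 0).any():
        bad = libs.index[libs <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    rel = counts.div(libs, axis=0)
    needed = math.ceil(min_frac_samples * counts.shape[0])
    n_hits = (rel >= min_rel).sum(axis=0)
    return list(counts.columns[(n_hits >= needed).to_numpy()])


def zscore(values) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (n-1 denominator).

    Raises on fewer than two observations or zero variance; the error names
    the offending series when it carries a pandas name.
    """
    arr = np.asarray(values, dtype=float)
    name = getattr(values, "name", None)
    label = f" ({name})" if name is not None else ""
    if arr.size < 2:
        raise ValueError(f"need at least 2 values to standardize{label}")
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"zero or undefined variance, cannot standardize{label}")
    out = (arr - arr.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=name)
    return out


def presence_flag(counts: pd.DataFrame, taxon_id) -> pd.Series:
    """Binary presence of a taxon per sample, from *raw* counts (count > 0)."""
    validate_count_table(counts)
    if taxon_id not in counts.columns:
        raise KeyError(f"unknown taxon id: {taxon_id!r}")
    return (counts[taxon_id] > 0).astype(int).rename(f"present_{taxon_id}")


_BRISTOL_GROUPS = {1: "hard", 2: "hard", 3: "medium", 4: "medium", 5: "medium", 6: "loose", 7: "loose"}


def bristol_group(stool_type: int) -> str:
    """Collapse the 7-point Bristol stool scale: hard (1-2), medium (3-5), loose (6-7)."""
    try:
        t = int(stool_type)
    except (TypeError, ValueError):
        raise ValueError(f"Bristol type must be an integer 1-7, got {stool_type!r}")
    if t != stool_type or t not in _BRISTOL_GROUPS:
        raise ValueError(f"Bristol type must be an integer 1-7, got {stool_type!r}")
    return _BRISTOL_GROUPS[t]
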