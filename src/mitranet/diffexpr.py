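"""Small-RNA differential expression with a dual p-value/fold-change gate.

Counts are normalized to counts-per-million per sample, each miRNA is
compared between two groups with a normality-driven two-sample test, and a
miRNA is called differential only when p < alpha AND the linear fold change
clears the threshold strictly (FC > t for up, FC < 1/t for down).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import compare_two

logger = logging.getLogger(__name__)

__all__ = [
    "SignedMiRNASet",
    "DEResult",
    "canonical_mirna",
    "normalize",
    "test_mirna",
    "call_de",
    "parse_signed_list",
    "de_table",
]

DEFAULT_ALPHA = 0.05
DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_PSEUDOCOUNT = 0.5  # CPM added to both group means before the ratio


def canonical_mirna(name: str, species: str = "rno") -> str:
    """Canonical lowercase miRNA id with species prefix expansion.

    Bare suffixes get the implicit ``<species>-mir-`` prefix ("23a-5p" ->
    "rno-mir-23a-5p"); matching is case-insensitive; arm suffixes are kept
    verbatim.
    """
    token = name.strip().strip("*").lower()
    if not token:
        raise ValueError("empty miRNA name")
    if token.startswith(("mir-", "let-")):
        return f"{species}-{token}"
    if re.match(r"^[a-z]{3,4}-", token):
        return token
    return f"{species}-mir-{token}"


@dataclass
class SignedMiRNASet:
    """Differentially expressed miRNAs split by direction."""

    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        both = self.up & self.down
        if both:
            raise ValueError(f"miRNAs in both directions: {sorted(both)}")

    def direction(self, mirna_id: str) -> str | None:
        if mirna_id in self.up:
            return "up"
        if mirna_id in self.down:
            return "down"
        return None

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass(frozen=True)
class DEResult:
    mirna_id: str
    mean_a: float  # normalized (CPM) group means
    mean_b: float
    fold_change: float  # B over A, linear scale
    p_value: float
    direction: str  # up | down | none


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample column; zero counts stay zero."""
    lib_sizes = counts.sum(axis=0)
    zero = lib_sizes[lib_sizes <= 0]
    if len(zero):
        raise ValueError(f"all-zero samples: {list(zero.index)}")
    return counts.div(lib_sizes, axis=1) * 1e6


def test_mirna(values_a, values_b, method: str = "auto") -> float:
    """Two-sided p-value for one miRNA between two groups."""
    return compare_two(values_a, values_b, method=method).p_value


def _fold_change(mean_a: float, mean_b: float, pseudocount: float) -> float:
    return (mean_b + pseudocount) / (mean_a + pseudocount)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_de(
    counts: pd.DataFrame,
    groups: pd.Series | dict[str, str],
    group_a: str,
    group_b: str,
    alpha: float = DEFAULT_ALPHA,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    method: str = "auto",
    correction: str | None = None,
) -> tuple[pd.DataFrame, SignedMiRNASet]:
    """Call differential miRNAs of ``group_b`` relative to ``group_a``.

    Returns the full result table (one row per miRNA, including the volcano
    coordinates ``log2_fold_change`` and ``neg_log10_p``) and the signed set
    of calls.  ``correction="fdr_bh"`` applies Benjamini-Hochberg to the
    p-values before thresholding; the default is raw p-values.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    for g in (group_a, group_b):
        if g not in set(groups.values):
            raise ValueError(f"unknown group label {g!r}")
    if counts.index.has_duplicates:
        raise ValueError("duplicate miRNA ids in count matrix")
    samples_a = [s for s in counts.columns if groups.get(s) == group_a]
    samples_b = [s for s in counts.columns if groups.get(s) == group_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both groups need at least two samples")

    cpm = normalize(counts)
    mat_a = cpm[samples_a].to_numpy()
    mat_b = cpm[samples_b].to_numpy()

    p_values = np.array([
        test_mirna(mat_a[i], mat_b[i], method=method) for i in range(len(cpm))
    ])
    if correction == "fdr_bh":
        p_values = _bh_adjust(p_values)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    mean_a = mat_a.mean(axis=1)
    mean_b = mat_b.mean(axis=1)
    fc = _fold_change(mean_a, mean_b, pseudocount)

    direction = np.where(
        (p_values < alpha) & (fc > fc_threshold), "up",
        np.where((p_values < alpha) & (fc < 1.0 / fc_threshold), "down", "none"),
    )
    table = pd.DataFrame({
        "mirna_id": cpm.index,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "fold_change": fc,
        "log2_fold_change": np.log2(fc),
        "p_value": p_values,
        "neg_log10_p": -np.log10(np.maximum(p_values, np.finfo(float).tiny)),
        "direction": direction,
    }).set_index("mirna_id", drop=False)

    signed = SignedMiRNASet(
        up=set(table.loc[table.direction == "up", "mirna_id"]),
        down=set(table.loc[table.direction == "down", "mirna_id"]),
    )
    logger.info(
        "DE %s vs %s: %d up, %d down of %d miRNAs",
        group_b, group_a, len(signed.up), len(signed.down), len(table),
    )
    return table, signed


_SPLIT_RE = re.compile(r"[,\s;]+|(?:\band\b)")


def _tokenize(text: str) -> list[str]:
    return [t for t in _SPLIT_RE.split(text or "") if t and t != "and"]


def parse_signed_list(up_text: str, down_text: str, species: str = "rno") -> SignedMiRNASet:
    """Parse free-text up/down miRNA lists into a canonical signed set.

    Bare suffixes inherit the species prefix; duplicates within a list are
    dropped with a warning; a name in both lists is an error.
    """
    up, down = set(), set()
    for text, bucket, label in ((up_text, up, "up"), (down_text, down, "down")):
        for token in _tokenize(text):
            cid = canonical_mirna(token, species=species)
            if cid in bucket:
                logger.warning("duplicate %sregulated miRNA %s ignored", label, cid)
            bucket.add(cid)
    return SignedMiRNASet(up=up, down=down)


def de_table(results: pd.DataFrame, path) -> None:
    """Write the full DE table as TSV."""
    results.to_csv(path, sep="\t", index=False)
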