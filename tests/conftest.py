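"""Shared fixtures and independent test oracles."""

from __future__ import annotations

import numpy as np
import pytest

from mitranet.diffexpr import SignedMiRNASet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def signed_small():
    return SignedMiRNASet(
        up={f"rno-mir-{i:04d}-5p" for i in range(8)},
        down={f"rno-mir-{i:04d}-5p" for i in range(8, 12)},
    )


def brute_force_strengths(records, signed) -> dict[str, int]:
    """Independent node-strength oracle: dedup pairs, count signed incidences.

    ``records`` is any iterable with ``mirna_id``/``gene_id`` attributes
    (already thresholded).  Kept deliberately simple and separate from the
    network implementation.
    """
    seen: set[tuple[str, str]] = set()
    strengths: dict[str, int] = {}
    for rec in records:
        pair = (rec.mirna_id, rec.gene_id)
        if pair in seen:
            continue
        seen.add(pair)
        if rec.mirna_id in signed.up:
            strengths[rec.gene_id] = strengths.get(rec.gene_id, 0) + 1
        elif rec.mirna_id in signed.down:
            strengths[rec.gene_id] = strengths.get(rec.gene_id, 0) - 1
    return strengths


def brute_force_from_tables(tables, signed,
                            mirdb_min=80.0, mirsvr_max=-1.2) -> dict[str, int]:
    """Oracle operating on the raw three-dialect tables, thresholds included."""

    class _Rec:
        def __init__(self, m, g):
            self.mirna_id, self.gene_id = m, g

    kept = []
    for dialect, df in tables.items():
        for row in df.itertuples():
            if dialect == "mirdb" and not row.score > mirdb_min:
                continue
            if dialect == "mirsvr" and not row.mirsvr_score < mirsvr_max:
                continue
            kept.append(_Rec(row.mirna, row.gene))
    return brute_force_strengths(kept, signed)
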