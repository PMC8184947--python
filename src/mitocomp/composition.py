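"""Base composition and strand-skew statistics.

AT skew = (A − T) / (A + T) and GC skew = (G − C) / (G + C), computed on
counts with N excluded.  A positive AT skew means A-rich, negative means
T-rich; a positive GC skew means G-rich.  When a denominator is zero the
corresponding skew is ``None`` and flagged, never silently 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genbank_io import AnalysisError, MitogenomeRecord
from .genome_model import PARTITION_LABELS, extract_partition


@dataclass
class CompositionStats:
    length_counted: int  # N excluded
    a: int
    c: int
    g: int
    t: int
    at_content: float
    gc_content: float
    at_skew: float | None  # None when A+T == 0
    gc_skew: float | None  # None when G+C == 0

    @property
    def undefined_at_skew(self) -> bool:
        return self.at_skew is None

    @property
    def undefined_gc_skew(self) -> bool:
        return self.gc_skew is None


def base_composition(sequence: str) -> CompositionStats:
    """Composition and skews of one DNA string (N bases excluded)."""
    counts = Counter(sequence.upper())
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    n = a + c + g + t
    if n == 0:
        raise AnalysisError("no countable bases (empty or all-N sequence)")
    at, gc = a + t, g + c
    return CompositionStats(
        length_counted=n, a=a, c=c, g=g, t=t,
        at_content=at / n, gc_content=gc / n,
        at_skew=(a - t) / at if at else None,
        gc_skew=(g - c) / gc if gc else None,
    )


def combine(parts: list[CompositionStats]) -> CompositionStats:
    """Stats of a concatenation, from summed counts of its parts."""
    a = sum(p.a for p in parts)
    c = sum(p.c for p in parts)
    g = sum(p.g for p in parts)
    t = sum(p.t for p in parts)
    n = a + c + g + t
    if n == 0:
        raise AnalysisError("no countable bases")
    at, gc = a + t, g + c
    return CompositionStats(n, a, c, g, t, at / n, gc / n,
                            (a - t) / at if at else None,
                            (g - c) / gc if gc else None)


def skew_profile(record: MitogenomeRecord,
                 labels: tuple[str, ...] = ("WHOLE", "PCG", "TRNA", "RRNA",
                                            "HEAVY", "LIGHT")) -> pd.DataFrame:
    """One composition row per partition of the record.

    Partitions with no matching features (e.g. LIGHT on an all-heavy
    record) are reported as null rows rather than dropped.
    """
    rows = []
    for label in labels:
        try:
            part = extract_partition(record, label)
            s = base_composition(part.sequence)
            rows.append({
                "partition": label, "length": s.length_counted,
                "A": s.a, "C": s.c, "G": s.g, "T": s.t,
                "at_content": s.at_content, "gc_content": s.gc_content,
                "at_skew": s.at_skew, "gc_skew": s.gc_skew,
            })
        except AnalysisError:
            rows.append({"partition": label, "length": 0,
                         "A": None, "C": None, "G": None, "T": None,
                         "at_content": None, "gc_content": None,
                         "at_skew": None, "gc_skew": None})
    return pd.DataFrame(rows).set_index("partition")


def skew_profile_tsv(profile: pd.DataFrame, percent: bool = True) -> str:
    """Human-readable TSV: contents as percentages, skews to 3 decimals."""
    df = profile.copy()
    for col in ("at_content", "gc_content"):
        if percent:
            df[col] = df[col].map(lambda v: f"{100 * v:.1f}" if pd.notna(v) else "NA")
        else:
            df[col] = df[col].map(lambda v: f"{v:.4f}" if pd.notna(v) else "NA")
    for col in ("at_skew", "gc_skew"):
        df[col] = df[col].map(lambda v: f"{v:.3f}" if pd.notna(v) else "NA")
    return df.to_csv(sep="\t")
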