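"""Partitioning a mitogenome into the compartments used for comparison.

The compartments are: the whole genome, the concatenated protein-coding
genes (PCG), tRNAs, rRNAs, the heavy- and light-strand gene sets (each
gene taken in coding orientation), and the non-coding remainder.  Gene
concatenations follow genome order; positions shared by two overlapping
genes contribute to both genes' partitions, while the genome-coverage
statistic counts each position once (union of feature positions).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genbank_io import (
    AnalysisError,
    GeneFeature,
    MitogenomeRecord,
    PCG,
    RRNA,
    TRNA,
)

PARTITION_LABELS = ("WHOLE", "PCG", "TRNA", "RRNA", "HEAVY", "LIGHT", "NONCODING")


@dataclass
class Partition:
    label: str
    sequence: str
    source: list[tuple[str, tuple[int, int]]]  # (feature name, (start, end))


@dataclass
class IntergenicRegion:
    upstream_gene: str
    downstream_gene: str
    start: int
    end: int  # half-open; may wrap: end <= start means the region spans the origin
    length: int
    at_content: float


def _select_features(record: MitogenomeRecord, label: str) -> list[GeneFeature]:
    if label == "PCG":
        return record.features_of_class(PCG)
    if label == "TRNA":
        return record.features_of_class(TRNA)
    if label == "RRNA":
        return record.features_of_class(RRNA)
    if label == "HEAVY":
        return [f for f in record.features if f.strand == +1]
    if label == "LIGHT":
        return [f for f in record.features if f.strand == -1]
    feat = record.get_feature(label)
    if feat is not None:
        return [feat]
    return []


def extract_partition(record: MitogenomeRecord, label: str) -> Partition:
    """Concatenate the sequence of one genome compartment.

    Gene-based partitions concatenate features in genome order, each in
    coding orientation (light-strand genes reverse-complemented).
    """
    if label == "WHOLE":
        return Partition("WHOLE", record.sequence, [(record.id, (0, len(record)))])
    if label == "NONCODING":
        regions = noncoding_regions(record)
        if not regions:
            raise AnalysisError("empty partition: NONCODING (features tile the genome)")
        seq = "".join(_region_slice(record, r) for r in regions)
        return Partition("NONCODING",
                         seq, [("intergenic", (r.start, r.end)) for r in regions])
    feats = _select_features(record, label)
    if not feats:
        raise AnalysisError(f"empty partition: no features match label {label!r}")
    seq = "".join(record.feature_sequence(f) for f in feats)
    return Partition(label, seq, [(f.name, (f.start, f.end)) for f in feats])


def _region_slice(record: MitogenomeRecord, region: IntergenicRegion) -> str:
    if region.end > region.start:
        return record.sequence[region.start: region.end]
    return record.sequence[region.start:] + record.sequence[: region.end]


def coverage_mask(record: MitogenomeRecord) -> list[bool]:
    covered = [False] * len(record)
    for f in record.features:
        for p in f.positions(len(record)):
            covered[p] = True
    return covered


def coverage_fraction(record: MitogenomeRecord) -> float:
    """Fraction of genome positions covered by at least one feature."""
    mask = coverage_mask(record)
    return sum(mask) / len(mask)


def noncoding_regions(record: MitogenomeRecord) -> list[IntergenicRegion]:
    """Maximal runs of positions covered by no feature, with flanking genes.

    On a circular record the run spanning the origin is reported once,
    with ``end <= start`` marking the wrap.
    """
    from .composition import base_composition

    L = len(record)
    mask = coverage_mask(record)
    if all(mask):
        return []
    if not any(mask):
        return [IntergenicRegion("", "", 0, L, L,
                                 base_composition(record.sequence).at_content)]

    # runs of uncovered positions on the line
    runs: list[list[int]] = []
    i = 0
    while i < L:
        if not mask[i]:
            j = i
            while j < L and not mask[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    # merge a run touching the end with a run starting at 0 on the circle
    if record.circular and len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == L:
        first = runs.pop(0)
        runs[-1][1] = first[1]  # wrapped region [start, L) U [0, end)

    def covering_feature(pos: int) -> str:
        for f in record.features:
            if pos in set(f.positions(L)) or (
                not f.wraps_origin and f.start <= pos < f.end):
                return f.name
        return ""

    regions = []
    for start, end in runs:
        wraps = end <= start or end > L
        end = end % L if end >= L and record.circular else end
        length = (end - start) if end > start else (L - start + end)
        seq = (record.sequence[start:end] if end > start
               else record.sequence[start:] + record.sequence[:end])
        up = covering_feature((start - 1) % L)
        down = covering_feature(end % L)
        regions.append(IntergenicRegion(up, down, start, end, length,
                                        base_composition(seq).at_content))
    return regions


def noncoding_total(record: MitogenomeRecord) -> int:
    return sum(r.length for r in noncoding_regions(record))


def overlap_report(record: MitogenomeRecord) -> list[tuple[str, str, int]]:
    """Pairwise overlaps between genome-order-adjacent features.

    Returns ``(upstream_name, downstream_name, overlap_nt)`` for every
    adjacent pair whose position sets intersect, including the wrap-around
    pair on a circular record.  A position covered by three features at
    once triggers a warning (the length bookkeeping identity assumes pair
    overlaps only).
    """
    import logging

    L = len(record)
    feats = record.features
    if len(feats) < 2:
        return []
    depth = [0] * L
    for f in feats:
        for p in f.positions(L):
            depth[p] += 1
    if any(d > 2 for d in depth):
        logging.getLogger("mitocomp").warning("triple overlap detected")

    out = []
    n = len(feats)
    for i in range(n):
        a, b = feats[i], feats[(i + 1) % n]
        if i + 1 == n and not record.circular:
            break
        inter = set(a.positions(L)) & set(b.positions(L))
        if inter:
            out.append((a.name, b.name, len(inter)))
    return out


def feature_length_sum(record: MitogenomeRecord) -> int:
    return sum(f.length(len(record)) for f in record.features)


def partitions_to_fasta(record: MitogenomeRecord, labels=PARTITION_LABELS) -> str:
    """Multi-FASTA export of the requested partitions (missing ones skipped)."""
    chunks = []
    for label in labels:
        try:
            p = extract_partition(record, label)
        except AnalysisError:
            continue
        chunks.append(f">{record.id}|{label}\n")
        for i in range(0, len(p.sequence), 70):
            chunks.append(p.sequence[i: i + 70] + "\n")
    return "".join(chunks)


def intergenic_table(record: MitogenomeRecord) -> str:
    rows = ["upstream_gene\tdownstream_gene\tstart\tend\tlength\tat_content"]
    for r in noncoding_regions(record):
        rows.append(f"{r.upstream_gene}\t{r.downstream_gene}\t{r.start + 1}\t"
                    f"{r.end}\t{r.length}\t{r.at_content:.3f}")
    return "\n".join(rows) + "\n"
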