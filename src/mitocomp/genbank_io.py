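"""Reading and writing annotated mitochondrial genomes.

The internal data model is a :class:`MitogenomeRecord`: an uppercase DNA
sequence plus an ordered list of :class:`GeneFeature` annotations.  All
internal coordinates are 0-based half-open; GenBank flat files and TSV
feature tables use the conventional 1-based inclusive coordinates, with
``complement(...)`` marking light-strand genes and ``join(...)`` marking
features that span the origin of a circular genome.

Gene names are canonicalized through a synonym table shipped with the
package (``data/gene_synonyms.tsv``) so that records annotated with the
ND/NAD or COI/COX1 spelling families compare as equal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mitocomp")

VALID_BASES = set("ACGTN")
PCG, TRNA, RRNA, DLOOP, OTHER = "PCG", "TRNA", "RRNA", "DLOOP", "OTHER"
GENE_CLASSES = (PCG, TRNA, RRNA, DLOOP, OTHER)

#: canonical names of the 13 mitochondrial protein-coding genes
PCG_NAMES = (
    "COX1", "COX2", "COX3", "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L",
    "NAD5", "NAD6", "ATP6", "ATP8", "CYTB",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MitocompError(Exception):
    """Base class for all package errors."""


class InputError(MitocompError):
    """Malformed or missing input data."""


class AnalysisError(MitocompError):
    """A computation could not be carried out on valid-looking input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# gene-name canonicalization
# ---------------------------------------------------------------------------

def _load_synonyms() -> dict[str, str]:
    table = {}
    text = resources.files("mitocomp").joinpath("data/gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        alias, canonical = line.rstrip("\n").split("\t")[:2]
        table[_normalize_key(alias)] = canonical
        table.setdefault(_normalize_key(canonical), canonical)
    return table


def _normalize_key(name: str) -> str:
    return re.sub(r"[\s_\-()]", "", name).upper()


_SYNONYMS: dict[str, str] | None = None


def canonical_gene_name(name: str, extra: dict[str, str] | None = None) -> str:
    """Map a gene name or product string to its canonical symbol.

    Unrecognized names are returned unchanged (stripped), so user-defined
    features survive a round trip.  ``extra`` augments the shipped table.
    """
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    key = _normalize_key(name)
    if extra:
        extended = {_normalize_key(k): v for k, v in extra.items()}
        if key in extended:
            return extended[key]
    return _SYNONYMS.get(key, name.strip())


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class GeneFeature:
    """One annotated gene on a mitogenome.

    ``start``/``end`` are 0-based half-open genome coordinates.  For a
    feature that spans the origin of a circular genome ``wraps_origin`` is
    true and the covered segment is ``[start, L) ∪ [0, end)``.
    """

    name: str
    gene_class: str
    start: int
    end: int
    strand: int  # +1 heavy, -1 light
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise InputError(f"unknown gene class {self.gene_class!r}")
        if self.strand not in (+1, -1):
            raise InputError(f"strand must be +1 or -1, got {self.strand!r}")
        if not self.wraps_origin and self.end <= self.start:
            raise InputError(
                f"feature {self.name}: end must exceed start unless it wraps the origin"
            )

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + self.end
        return self.end - self.start

    def positions(self, genome_length: int) -> Iterable[int]:
        """Genome positions covered, 5'->3' on the heavy strand."""
        if self.wraps_origin:
            yield from range(self.start, genome_length)
            yield from range(0, self.end)
        else:
            yield from range(self.start, self.end)


@dataclass
class MitogenomeRecord:
    id: str
    description: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise InputError("no sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise InputError(f"sequence contains invalid characters: {sorted(bad)}")
        L = len(self.sequence)
        for f in self.features:
            if f.wraps_origin and not self.circular:
                raise InputError(f"feature {f.name} wraps origin of a linear record")
            hi = max(f.start, f.end if not f.wraps_origin else 0)
            if f.start >= L or (not f.wraps_origin and f.end > L) or hi > L:
                raise InputError(f"coordinate out of range for feature {f.name}")
        self.features.sort(key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.sequence)

    # -- feature access -----------------------------------------------------

    def feature_slice(self, feat: GeneFeature) -> str:
        """Heavy-strand genome slice covered by the feature."""
        if feat.wraps_origin:
            return self.sequence[feat.start:] + self.sequence[: feat.end]
        return self.sequence[feat.start: feat.end]

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Feature sequence 5'->3' in coding orientation."""
        s = self.feature_slice(feat)
        return s if feat.strand == +1 else reverse_complement(s)

    def features_of_class(self, gene_class: str) -> list[GeneFeature]:
        return [f for f in self.features if f.gene_class == gene_class]

    def get_feature(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def rotated(self, offset: int) -> "MitogenomeRecord":
        """Record with the origin moved forward by ``offset`` positions.

        Only meaningful for circular records; gene content is unchanged.
        """
        if not self.circular:
            raise InputError("cannot rotate a linear record")
        L = len(self.sequence)
        offset %= L
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            length = f.length(L)
            start = (f.start - offset) % L
            end = start + length
            wraps = end > L
            feats.append(
                GeneFeature(f.name, f.gene_class, start, end % L if wraps else end,
                            f.strand, wraps_origin=wraps)
            )
        return MitogenomeRecord(self.id, self.description, seq, True, feats)


# ---------------------------------------------------------------------------
# GenBank input
# ---------------------------------------------------------------------------

_FEATURE_KEY_CLASS = {"CDS": PCG, "tRNA": TRNA, "rRNA": RRNA, "D-loop": DLOOP}


def _feature_name(sf: SeqFeature) -> str:
    for key in ("gene", "product", "note", "locus_tag"):
        vals = sf.qualifiers.get(key)
        if vals:
            return str(vals[0])
    return sf.type


def _location_to_coords(loc, genome_length: int, circular: bool):
    """(start, end, strand, wraps) from a biopython location."""
    strand = +1 if (loc.strand is None or loc.strand >= 0) else -1
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    parts = sorted(parts, key=lambda p: int(p.start))
    if len(parts) == 1:
        return int(parts[0].start), int(parts[0].end), strand, False
    # join across the origin: one part ends at L, the other starts at 0
    if (
        len(parts) == 2
        and circular
        and int(parts[1].end) == genome_length
        and int(parts[0].start) == 0
    ):
        return int(parts[1].start), int(parts[0].end), strand, True
    raise InputError(f"unsupported compound location {loc}")


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Parse a GenBank flat file into the internal model.

    CDS features become PCGs; tRNA/rRNA/D-loop keep their class; plain
    ``gene`` features that duplicate a typed feature at the same locus are
    merged away.  Unknown feature keys are skipped with a warning.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise InputError(f"cannot parse GenBank file {path}: {exc}") from exc
    try:
        seq = str(rec.seq)
    except Exception as exc:  # undefined sequence (no ORIGIN block)
        raise InputError("no sequence") from exc
    if not seq:
        raise InputError("no sequence")
    circular = rec.annotations.get("topology", "circular") == "circular"
    L = len(seq)

    feats: list[GeneFeature] = []
    plain_genes: list[GeneFeature] = []
    for sf in rec.features:
        if sf.type == "source":
            continue
        if sf.type not in _FEATURE_KEY_CLASS and sf.type != "gene":
            logger.warning("skipping feature of unknown key %r", sf.type)
            continue
        try:
            start, end, strand, wraps = _location_to_coords(sf.location, L, circular)
        except InputError:
            logger.warning("skipping feature with unsupported location: %s", sf)
            continue
        if not circular and end > L:
            raise InputError(f"coordinate out of range in feature {sf}")
        name = canonical_gene_name(_feature_name(sf))
        gf = GeneFeature(name, _FEATURE_KEY_CLASS.get(sf.type, OTHER),
                         start, end, strand, wraps_origin=wraps)
        (plain_genes if sf.type == "gene" else feats).append(gf)

    # merge gene/CDS duplicate pairs: keep the typed feature
    typed_loci = {(f.name, f.start) for f in feats}
    typed_names = {f.name for f in feats}
    for g in plain_genes:
        if (g.name, g.start) in typed_loci or g.name in typed_names:
            continue
        feats.append(g)

    return MitogenomeRecord(rec.id or rec.name, rec.description or "", seq,
                            circular, feats)


# ---------------------------------------------------------------------------
# FASTA + TSV feature table
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ("name", "class", "start", "end", "strand")


def read_fasta_with_table(fasta: str | Path, table: str | Path,
                          circular: bool = True) -> MitogenomeRecord:
    """Load a genome from a FASTA file and a sidecar TSV feature table.

    The table has columns ``name  class  start  end  strand`` with 1-based
    inclusive coordinates; a row with ``end < start`` denotes an
    origin-spanning feature on a circular genome.
    """
    rec = SeqIO.read(str(fasta), "fasta")
    seq = str(rec.seq).upper()
    feats = []
    with open(table) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip().lower() for c in cells]
                missing = set(TABLE_COLUMNS) - set(header)
                if missing:
                    raise InputError(f"feature table missing columns {sorted(missing)}")
                continue
            row = dict(zip(header, cells))
            start1, end1 = int(row["start"]), int(row["end"])
            strand = +1 if row["strand"] in ("+", "1", "+1") else -1
            wraps = end1 < start1
            if wraps and not circular:
                raise InputError(f"malformed feature row for {row['name']}: end < start")
            feats.append(GeneFeature(
                canonical_gene_name(row["name"]), row["class"].upper(),
                start1 - 1, end1, strand, wraps_origin=wraps))
    return MitogenomeRecord(rec.id, rec.description, seq, circular, feats)


def write_feature_table(record: MitogenomeRecord) -> str:
    """Render the gene table: one row per feature in genome order.

    ``spacer_to_next`` is the number of nucleotides separating a feature
    from the next one in genome order (negative = overlap), computed on the
    circle for circular records.  PCG rows carry their start codon and stop
    codon (an incomplete stop is padded with ``-``).
    """
    from .codon_usage import start_and_stop  # local import avoids a cycle

    L = len(record)
    rows = ["name\tclass\tstrand\tstart\tend\tlength\tspacer_to_next\tstart_codon\tstop_codon"]
    feats = record.features
    for i, f in enumerate(feats):
        if i + 1 < len(feats):
            nxt = feats[i + 1]
            spacer = nxt.start - (f.start + f.length(L))
        else:
            nxt = feats[0]
            fin = f.start + f.length(L)
            spacer = (nxt.start + (L if record.circular else 0)) - fin
        start_c = stop_c = ""
        if f.gene_class == PCG:
            start_c, stop_c = start_and_stop(record.feature_sequence(f))
        end1 = f.end if not f.wraps_origin else f.end  # wrapped end is already 1-based-exclusive head
        rows.append("\t".join([
            f.name, f.gene_class, "+" if f.strand == +1 else "-",
            str(f.start + 1), str(end1), str(f.length(L)),
            f"{spacer:+d}" if spacer else "0", start_c, stop_c,
        ]))
    return "\n".join(rows) + "\n"


def write_fasta(record: MitogenomeRecord, path: str | Path) -> None:
    SeqIO.write(SeqRecord(Seq(record.sequence), id=record.id,
                          description=record.description), str(path), "fasta")


def write_table(record: MitogenomeRecord, path: str | Path) -> None:
    Path(path).write_text(write_feature_table(record))


_CLASS_FEATURE_KEY = {PCG: "CDS", TRNA: "tRNA", RRNA: "rRNA", DLOOP: "D-loop",
                      OTHER: "gene"}


def write_genbank(record: MitogenomeRecord, path: str | Path) -> None:
    """Write the record as a GenBank flat file (round-trips through
    :func:`read_genbank`)."""
    L = len(record)
    sr = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                   description=record.description)
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["topology"] = "circular" if record.circular else "linear"
    strand_of = lambda f: 1 if f.strand == +1 else -1
    for f in record.features:
        if f.wraps_origin:
            tail = SimpleLocation(f.start, L, strand_of(f))
            head = SimpleLocation(0, f.end, strand_of(f))
            order = [tail, head] if f.strand == +1 else [head, tail]
            loc = CompoundLocation(order)
        else:
            loc = SimpleLocation(f.start, f.end, strand_of(f))
        sf = SeqFeature(loc, type=_CLASS_FEATURE_KEY[f.gene_class])
        sf.qualifiers["gene"] = [f.name]
        sr.features.append(sf)
    SeqIO.write(sr, str(path), "genbank")


def copy_record(record: MitogenomeRecord) -> MitogenomeRecord:
    return MitogenomeRecord(record.id, record.description, record.sequence,
                            record.circular, [replace(f) for f in record.features])
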