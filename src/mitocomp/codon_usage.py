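"""Translation and relative synonymous codon usage (RSCU).

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial: ATA = Met, TGA = Trp, AGA/AGG = Ser, alternative starts
such as GTG).  RSCU is codon count divided by the expected count under
uniform usage within the codon's synonymous family; synonymous families
are defined by (amino acid, first-two-nucleotide block) under the active
code, so six-fold leucine splits into Leu1 (CUN) and Leu2 (UUR) and the
eight serine codons of table 5 split into Ser1 (AGN) and Ser2 (UCN) — the
split conventionally used when ranking mitochondrial codon usage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .genbank_io import AnalysisError, MitogenomeRecord, PCG

_BASES = "TCAG"
AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Stop",
}

# conventional numbering of the split families (first two codon bases -> suffix)
_BLOCK_SUFFIX = {("L", "CT"): "1", ("L", "TT"): "2",
                 ("S", "AG"): "1", ("S", "TC"): "2"}


@dataclass(frozen=True)
class GeneticCode:
    id: int
    codon_to_aa: dict[str, str]  # 64 entries, stops map to "*"
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    @classmethod
    def from_table(cls, table_id: int = 5) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(t.forward_table)
        for stop in t.stop_codons:
            mapping[stop] = "*"
        assert len(mapping) == 64
        return cls(table_id, mapping, frozenset(t.start_codons),
                   frozenset(t.stop_codons))

    def family_key(self, codon: str) -> tuple[str, str]:
        """(amino acid, first-two-nucleotide block) identifying the
        synonymous family of a codon."""
        aa = self.codon_to_aa[codon]
        blocks = {c[:2] for c, a in self.codon_to_aa.items() if a == aa}
        if len(blocks) == 1:
            return (aa, "")
        return (aa, codon[:2])

    def family_label(self, codon: str) -> str:
        aa, block = self.family_key(codon)
        name = AA3.get(aa, aa)
        return name + _BLOCK_SUFFIX.get((aa, block), "" if not block else block)

    def family_codons(self, codon: str) -> list[str]:
        key = self.family_key(codon)
        return sorted(c for c in self.codon_to_aa if self.family_key(c) == key)


INVERTEBRATE_MITO = GeneticCode.from_table(5)


@dataclass
class TranslationResult:
    protein: str
    incomplete_stop: str  # trailing 1-2 nt remainder, "" when in frame
    internal_stops: list[int]  # codon indices of internal stop codons

    def __str__(self) -> str:
        return self.protein


def translate(cds: str, code: GeneticCode = INVERTEBRATE_MITO) -> TranslationResult:
    """Translate in frame 0; tolerate a 1-2 nt trailing remainder.

    A trailing remainder signals an incomplete stop codon (completed by
    polyadenylation in mitochondrial transcripts) and is reported, not
    raised.  Codons containing N or other ambiguity translate to ``X``.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise AnalysisError("no complete codon")
    n_codons = len(cds) // 3
    remainder = cds[3 * n_codons:]
    aas = []
    internal = []
    for i in range(n_codons):
        codon = cds[3 * i: 3 * i + 3]
        aa = code.codon_to_aa.get(codon, "X")
        if aa == "*" and i < n_codons - 1:
            internal.append(i)
        aas.append(aa)
    return TranslationResult("".join(aas), remainder, internal)


def start_and_stop(cds: str) -> tuple[str, str]:
    """First codon and the (possibly incomplete, '-'-padded) final codon."""
    if len(cds) < 3:
        return cds, ""
    start = cds[:3]
    r = len(cds) % 3
    stop = cds[-3:] if r == 0 else cds[-r:] + "-" * (3 - r)
    return start, stop


def start_stop_table(record: MitogenomeRecord,
                     code: GeneticCode = INVERTEBRATE_MITO) -> pd.DataFrame:
    """Start codon, stop codon and completeness flag per PCG, genome order."""
    pcgs = record.features_of_class(PCG)
    if not pcgs:
        raise AnalysisError("record has no PCG features")
    rows = []
    for f in pcgs:
        seq = record.feature_sequence(f)
        if len(seq) < 6:
            rows.append({"gene": f.name, "start_codon": "", "stop_codon": "",
                         "complete_stop": False, "flagged": True})
            continue
        start, stop = start_and_stop(seq)
        rows.append({
            "gene": f.name,
            "start_codon": start,
            "stop_codon": stop,
            "complete_stop": "-" not in stop and stop in code.stop_codons,
            "flagged": False,
        })
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class CodonUsageTable:
    code_id: int
    table: pd.DataFrame  # index codon; columns amino_acid, family, count, rscu
    total_codons: int
    include_stops: bool = False

    def rscu_of(self, codon: str) -> float:
        return float(self.table.loc[codon.upper().replace("U", "T"), "rscu"])

    def ranked(self, k: int = 5) -> dict[str, list[dict]]:
        """Top-k and bottom-k codons by RSCU.

        Ties break by higher raw count, then alphabetical codon.  Codons in
        families with zero usage are excluded.
        """
        df = self.table.dropna(subset=["rscu"])
        records = [
            {"codon": c, "family": r["family"], "count": int(r["count"]),
             "rscu": float(r["rscu"])}
            for c, r in df.iterrows()
        ]
        top = sorted(records, key=lambda r: (-r["rscu"], -r["count"], r["codon"]))
        bottom = sorted(records, key=lambda r: (r["rscu"], r["count"], r["codon"]))
        return {"top": top[:k], "bottom": bottom[:k]}

    def to_tsv(self) -> str:
        df = self.table.copy()
        df["rscu"] = df["rscu"].map(lambda v: f"{v:.4f}" if pd.notna(v) else "NA")
        return df.to_csv(sep="\t")


def _codon_iter(cds: str, code: GeneticCode):
    """Complete codons of a CDS, excluding the terminal stop and any codon
    containing a non-ACGT character."""
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i: 3 * i + 3]
        if i == n_codons - 1 and codon in code.stop_codons:
            continue
        if any(b not in "ACGT" for b in codon):
            continue
        yield codon


def count_codons(cds_sequences, code: GeneticCode = INVERTEBRATE_MITO) -> Counter:
    counts: Counter = Counter()
    for cds in cds_sequences:
        counts.update(_codon_iter(cds.upper(), code))
    return counts


def rscu(source, code: GeneticCode = INVERTEBRATE_MITO,
         include_stops: bool = False) -> CodonUsageTable:
    """Codon counts and RSCU pooled over protein-coding sequences.

    ``source`` may be a :class:`MitogenomeRecord` (all PCGs pooled), a list
    of records, or an iterable of CDS strings.  Stop codons receive counts
    but no RSCU value unless ``include_stops`` is set (a compatibility mode
    in which stops form their own family).
    """
    cds_seqs = _as_cds_list(source)
    counts = count_codons(cds_seqs, code)
    total = sum(counts.values())
    if total == 0:
        raise AnalysisError("empty usage table: no complete codons")

    all_codons = sorted(code.codon_to_aa)
    fam_totals: dict[tuple, int] = {}
    for c in all_codons:
        fam_totals.setdefault(code.family_key(c), 0)
        fam_totals[code.family_key(c)] += counts.get(c, 0)

    rows = []
    for c in all_codons:
        aa = code.codon_to_aa[c]
        fam = code.family_key(c)
        k = len(code.family_codons(c))
        n = fam_totals[fam]
        if aa == "*" and not include_stops:
            value = None
        elif n == 0:
            value = None
        else:
            value = counts.get(c, 0) * k / n
        rows.append({"codon": c, "amino_acid": AA3.get(aa, aa),
                     "family": code.family_label(c),
                     "count": counts.get(c, 0), "rscu": value})
    df = pd.DataFrame(rows).set_index("codon")
    counted = total if include_stops else total - sum(
        counts.get(c, 0) for c in code.stop_codons)
    return CodonUsageTable(code.id, df, counted, include_stops)


def rscu_per_gene(record: MitogenomeRecord,
                  code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, CodonUsageTable]:
    """Per-gene RSCU tables (alternative to pooling the 13 PCGs)."""
    out = {}
    for f in record.features_of_class(PCG):
        out[f.name] = rscu([record.feature_sequence(f)], code)
    return out


def _as_cds_list(source) -> list[str]:
    if isinstance(source, MitogenomeRecord):
        source = [source]
    seqs: list[str] = []
    items = list(source)
    for item in items:
        if isinstance(item, MitogenomeRecord):
            for f in item.features_of_class(PCG):
                seqs.append(item.feature_sequence(f))
        elif hasattr(item, "sequence"):  # Partition
            seqs.append(item.sequence)
        else:
            seqs.append(str(item))
    if not seqs:
        raise AnalysisError("empty usage table: no protein-coding input")
    return seqs
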