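"""Intra- and interspecific variation statistics on aligned mitogenomes.

Covers DnaSP-style accounting on alignments: SNP counts, indel sites and
events, nucleotide diversity π (average per-site pairwise difference) and
divergence k (average pairwise difference count), synonymous versus
nonsynonymous classification of codon columns, per-gene variation
profiles, pairwise divergence matrices, and neighbor-joining clustering.

Alignment policy: multiple sequence alignments are accepted as input
(gapped FASTA); only pairwise alignment is computed internally.  The
internal aligner is an affine-gap global aligner (Needleman–Wunsch /
Gotoh; a gap run of length ℓ costs ``gap_open + (ℓ-1)·gap_extend``) for
moderate lengths, with an edit-distance path (edlib) for genome-scale
pairs where the quadratic DP would be wasteful.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .genbank_io import (
    AnalysisError,
    InputError,
    MitogenomeRecord,
    PCG,
)
from .codon_usage import GeneticCode, INVERTEBRATE_MITO
from .genome_model import extract_partition

GAP = "-"
_IUPAC = set("ACGTNRYSWKMBDHV")


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]
    provenance: str = "external"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise InputError("alignment rows differ in length")
        self.rows = [r.upper() for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def columns(self):
        return zip(*self.rows)


def read_aligned_fasta(path) -> Alignment:
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise InputError(f"no sequences in {path}")
    return Alignment(ids, rows, provenance="external")


# ---------------------------------------------------------------------------
# pairwise global alignment (Gotoh affine)
# ---------------------------------------------------------------------------

#: default scoring: match +1, mismatch -1, gap open -2, gap extend -1
DEFAULT_ALIGN_PARAMS = {"match": 1.0, "mismatch": -1.0,
                        "gap_open": -2.0, "gap_extend": -1.0}

_M, _X, _Y = 0, 1, 2  # X: gap in b (consumes a); Y: gap in a (consumes b)
_NEG = float("-inf")


def global_align(a: str, b: str, match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -2.0, gap_extend: float = -1.0,
                 ids: tuple[str, str] = ("a", "b")) -> Alignment:
    """Optimal global alignment of two sequences under affine gap costs.

    Deterministic tie-breaking: on equal score, a match/mismatch step is
    preferred over a gap in ``a``, which is preferred over a gap in ``b``.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    for s in (a, b):
        bad = set(s) - _IUPAC
        if bad:
            raise InputError(f"non-IUPAC characters in input: {sorted(bad)}")

    n, m = len(a), len(b)
    # pointer[state][i][j] = predecessor state; rolling score rows
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    prev = np.full((3, m + 1), _NEG)
    prev[_M][0] = 0.0
    for j in range(1, m + 1):
        prev[_Y][j] = (gap_open if j == 1 else prev[_Y][j - 1] + gap_extend)
        ptr[_Y][0][j] = _M if j == 1 else _Y

    # tie preference when choosing the predecessor state: M, then Y, then X
    order = (_M, _Y, _X)

    def best(scores):
        s = max(scores[k] for k in order)
        for k in order:
            if scores[k] == s:
                return s, k
        raise AssertionError

    for i in range(1, n + 1):
        cur = np.full((3, m + 1), _NEG)
        if i == 1:
            cur[_X][0] = gap_open
            ptr[_X][i][0] = _M
        else:
            cur[_X][0] = prev[_X][0] + gap_extend
            ptr[_X][i][0] = _X
        ai = a[i - 1]
        for j in range(1, m + 1):
            s_sub = match if ai == b[j - 1] else mismatch
            sc, k = best({_M: prev[_M][j - 1], _X: prev[_X][j - 1],
                          _Y: prev[_Y][j - 1]})
            cur[_M][j] = sc + s_sub
            ptr[_M][i][j] = k
            sc, k = best({_M: prev[_M][j] + gap_open,
                          _X: prev[_X][j] + gap_extend,
                          _Y: prev[_Y][j] + gap_open})
            cur[_X][j] = sc
            ptr[_X][i][j] = k
            sc, k = best({_M: cur[_M][j - 1] + gap_open,
                          _X: cur[_X][j - 1] + gap_open,
                          _Y: cur[_Y][j - 1] + gap_extend})
            cur[_Y][j] = sc
            ptr[_Y][i][j] = k
        prev = cur

    final = {k: prev[k][m] for k in (_M, _X, _Y)}
    score, state = best(final)

    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        k = int(ptr[state][i][j])
        if state == _M:
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif state == _X:
            ra.append(a[i - 1]); rb.append(GAP); i -= 1
        else:
            ra.append(GAP); rb.append(b[j - 1]); j -= 1
        state = k
    aln = Alignment(list(ids), ["".join(reversed(ra)), "".join(reversed(rb))],
                    provenance="internal-pairwise")
    aln.score = score  # type: ignore[attr-defined]
    return aln


def align_score(a: str, b: str, **params) -> float:
    return global_align(a, b, **params).score  # type: ignore[attr-defined]


#: sequences longer than this on both sides are aligned with edlib
EDLIB_THRESHOLD = 3000


def align_pair(a: str, b: str, ids: tuple[str, str] = ("a", "b")) -> Alignment:
    """Align a pair, picking the exact affine aligner for moderate sizes
    and the edit-distance path for genome-scale sequences."""
    if a == b:
        return Alignment(list(ids), [a.upper(), b.upper()], "internal-pairwise")
    if len(a) > EDLIB_THRESHOLD and len(b) > EDLIB_THRESHOLD:
        return edlib_align(a, b, ids)
    return global_align(a, b, ids=ids)


def edlib_align(a: str, b: str, ids: tuple[str, str] = ("a", "b")) -> Alignment:
    a, b = a.upper(), b.upper()
    res = edlib.align(a, b, task="path", mode="NW")
    nice = edlib.getNiceAlignment(res, a, b)
    return Alignment(list(ids), [nice["query_aligned"], nice["target_aligned"]],
                     provenance="internal-pairwise")


# ---------------------------------------------------------------------------
# variant accounting
# ---------------------------------------------------------------------------

@dataclass
class VariationSummary:
    aligned_columns: int
    compared_columns: int  # gap- and N-free columns
    snp_count: int
    indel_sites: int
    indel_events: int
    pi: float
    k: float
    syn_substitutions: int | None = None
    nonsyn_substitutions: int | None = None
    aa_change_proportion: float | None = None


def count_variants(aln: Alignment) -> VariationSummary:
    """SNP / indel-site / indel-event counts on an alignment.

    A SNP is a gap- and N-free column with at least two distinct bases.
    An indel site is any column containing a gap; an indel event is a
    maximal run of consecutive gapped columns sharing the same set of
    gapped rows (a change in the gapped-row set starts a new event).
    """
    if aln.n_rows < 2:
        raise InputError("variant counting needs at least 2 rows")
    snp = sites = events = compared = 0
    prev_pattern: frozenset | None = None
    for col in aln.columns():
        gapped = frozenset(i for i, c in enumerate(col) if c == GAP)
        if gapped:
            sites += 1
            if gapped != prev_pattern:
                events += 1
            prev_pattern = gapped
        else:
            prev_pattern = None
            if "N" in col:
                continue
            compared += 1
            if len(set(col)) > 1:
                snp += 1
    pi, k, compared2 = nucleotide_diversity(aln) if compared else (0.0, 0.0, 0)
    return VariationSummary(len(aln), compared, snp, sites, events, pi, k)


def snp_positions(aln: Alignment) -> list[int]:
    """Coordinates of SNP columns in the first row's ungapped sequence."""
    if aln.n_rows < 2:
        raise InputError("variant counting needs at least 2 rows")
    out = []
    pos = 0
    for col in aln.columns():
        gap_free = GAP not in col and "N" not in col
        if gap_free and len(set(col)) > 1:
            out.append(pos)
        if col[0] != GAP:
            pos += 1
    return out


def snp_fraction_in_class(record: MitogenomeRecord, aln: Alignment,
                          gene_class: str = PCG) -> float:
    """Fraction of SNPs (first row = this record) falling inside features
    of the given class."""
    positions = snp_positions(aln)
    if not positions:
        raise AnalysisError("no SNPs in alignment")
    L = len(record)
    covered = set()
    for f in record.features:
        if f.gene_class == gene_class:
            covered.update(f.positions(L))
    return sum(p in covered for p in positions) / len(positions)


def nucleotide_diversity(aln: Alignment, gap_mode: str = "complete"
                         ) -> tuple[float, float, int]:
    """Nucleotide diversity π and divergence k.

    π is the average over all row pairs of (pairwise differences /
    compared columns); k is the average pairwise difference count.  Under
    ``complete`` deletion (the default, as in DnaSP) any column containing
    a gap or N in any row is excluded for every pair; under ``pairwise``
    deletion only the pair's own gap/N columns are excluded.

    Returns ``(pi, k, compared_columns)``; for pairwise deletion the
    reported column count is the minimum over pairs.
    """
    if aln.n_rows < 2:
        raise InputError("diversity needs at least 2 rows")
    rows = aln.rows

    def pair_stats(r1: str, r2: str, mask=None):
        diffs = sites = 0
        for idx, (x, y) in enumerate(zip(r1, r2)):
            if mask is not None and not mask[idx]:
                continue
            if mask is None and (x in (GAP, "N") or y in (GAP, "N")):
                continue
            sites += 1
            if x != y:
                diffs += 1
        return diffs, sites

    if gap_mode == "complete":
        mask = [all(c not in (GAP, "N") for c in col) for col in aln.columns()]
        compared = sum(mask)
        if compared == 0:
            raise AnalysisError("no comparable sites")
        pis, ks = [], []
        for r1, r2 in itertools.combinations(rows, 2):
            d, s = pair_stats(r1, r2, mask)
            ks.append(d)
            pis.append(d / s)
        return float(np.mean(pis)), float(np.mean(ks)), compared
    if gap_mode == "pairwise":
        pis, ks, mins = [], [], []
        for r1, r2 in itertools.combinations(rows, 2):
            d, s = pair_stats(r1, r2)
            if s == 0:
                raise AnalysisError("no comparable sites")
            ks.append(d)
            pis.append(d / s)
            mins.append(s)
        return float(np.mean(pis)), float(np.mean(ks)), min(mins)
    raise InputError(f"unknown gap mode {gap_mode!r}")


def classify_substitutions(gene_aln: Alignment,
                           code: GeneticCode = INVERTEBRATE_MITO,
                           mode: str = "per_codon_column"
                           ) -> tuple[int, int, float]:
    """Synonymous / nonsynonymous classification on a codon-aligned gene.

    Each gap- and N-free codon column is translated in every row; a
    variable codon column is synonymous when all translations agree and
    nonsynonymous otherwise.  The amino-acid-change proportion is, by
    default, nonsynonymous codon columns over all gap-free codon columns
    (``per_codon_column``); ``per_substitution`` reports nonsynonymous
    over variable codon columns instead.
    """
    if len(gene_aln) % 3 != 0:
        raise InputError(
            "alignment length not divisible by 3; supply a codon-aware "
            "alignment (frame 0)")
    if gene_aln.n_rows < 2:
        raise InputError("classification needs at least 2 rows")
    syn = nonsyn = gap_free = 0
    for c0 in range(0, len(gene_aln), 3):
        codons = [r[c0: c0 + 3] for r in gene_aln.rows]
        if any(GAP in cd or "N" in cd for cd in codons):
            continue
        gap_free += 1
        if len(set(codons)) == 1:
            continue
        aas = {code.codon_to_aa.get(cd, "X") for cd in codons}
        if len(aas) == 1:
            syn += 1
        else:
            nonsyn += 1
    if mode == "per_codon_column":
        proportion = nonsyn / gap_free if gap_free else 0.0
    elif mode == "per_substitution":
        variable = syn + nonsyn
        proportion = nonsyn / variable if variable else 0.0
    else:
        raise InputError(f"unknown proportion mode {mode!r}")
    return syn, nonsyn, proportion


# ---------------------------------------------------------------------------
# per-gene profiles and divergence matrices
# ---------------------------------------------------------------------------

def _gene_alignment(records: list[MitogenomeRecord], gene: str,
                    external: dict[str, Alignment] | None) -> Alignment | None:
    if external and gene in external:
        return external[gene]
    seqs = []
    for rec in records:
        f = rec.get_feature(gene)
        if f is None:
            return None
        seqs.append(rec.feature_sequence(f))
    ids = [r.id for r in records]
    if len({len(s) for s in seqs}) == 1:
        return Alignment(ids, seqs, "internal-pairwise")
    if len(seqs) == 2:
        return global_align(seqs[0], seqs[1], ids=(ids[0], ids[1]))
    return None  # unequal lengths with 3+ records need an external MSA


def per_gene_profile(records: list[MitogenomeRecord],
                     alignments: dict[str, Alignment] | None = None,
                     code: GeneticCode = INVERTEBRATE_MITO,
                     proportion_mode: str = "per_codon_column"
                     ) -> tuple[pd.DataFrame, list[str]]:
    """π and amino-acid-change proportion per protein-coding gene.

    ``alignments`` may supply externally computed per-gene MSAs (keyed by
    canonical gene name); otherwise genes of equal length are compared
    column-wise and pairs are aligned internally.  Genes missing from any
    record, or needing an MSA that was not supplied, get a flagged row.
    Returns the table and the gene ranking by decreasing π.
    """
    if len(records) < 2:
        raise InputError("profile needs at least 2 records")
    genes = [f.name for f in records[0].features_of_class(PCG)]
    rows = []
    for gene in genes:
        aln = _gene_alignment(records, gene, alignments)
        if aln is None:
            rows.append({"gene": gene, "pi": np.nan, "k": np.nan,
                         "syn": np.nan, "nonsyn": np.nan,
                         "aa_change_proportion": np.nan, "flagged": True})
            continue
        pi, k, _ = nucleotide_diversity(aln)
        trimmed = aln
        if len(aln) % 3:
            cut = len(aln) - len(aln) % 3
            trimmed = Alignment(aln.ids, [r[:cut] for r in aln.rows],
                                aln.provenance)
        syn, nonsyn, prop = classify_substitutions(trimmed, code,
                                                   proportion_mode)
        rows.append({"gene": gene, "pi": pi, "k": k, "syn": syn,
                     "nonsyn": nonsyn, "aa_change_proportion": prop,
                     "flagged": False})
    df = pd.DataFrame(rows).set_index("gene")
    ranking = list(df[~df["flagged"]].sort_values("pi", ascending=False).index)
    return df, ranking


@dataclass
class DivergenceMatrix:
    ids: list[str]
    k: pd.DataFrame          # average pairwise difference counts
    per_site: pd.DataFrame   # k / compared columns
    level: str

    def minimum_pair(self) -> tuple[str, str, float]:
        best = None
        for i, a in enumerate(self.ids):
            for b in self.ids[i + 1:]:
                v = float(self.k.loc[a, b])
                if best is None or v < best[2]:
                    best = (a, b, v)
        return best

    def nearest_neighbors(self) -> dict[str, str]:
        out = {}
        for a in self.ids:
            others = [b for b in self.ids if b != a]
            out[a] = min(others, key=lambda b: float(self.k.loc[a, b]))
        return out


def divergence_matrix(records: list[MitogenomeRecord],
                      level: str = "WHOLE") -> DivergenceMatrix:
    """Pairwise divergence k for whole genomes or concatenated PCGs.

    Equal-length pairs are compared column-wise; unequal pairs are aligned
    internally first.  Columns with a gap or N are excluded (complete
    deletion per pair).
    """
    if len(records) < 3:
        raise InputError("divergence matrix needs at least 3 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate taxon ids")
    seqs = {}
    for rec in records:
        if level == "WHOLE":
            seqs[rec.id] = rec.sequence
        elif level == "PCG":
            seqs[rec.id] = extract_partition(rec, "PCG").sequence
        else:
            raise InputError(f"unknown level {level!r}")
    n = len(ids)
    K = np.zeros((n, n))
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[ids[i]], seqs[ids[j]]
            if len(a) == len(b):
                aln = Alignment([ids[i], ids[j]], [a, b], "internal-pairwise")
            else:
                aln = align_pair(a, b, (ids[i], ids[j]))
            pi, k, _ = nucleotide_diversity(aln)
            K[i, j] = K[j, i] = k
            P[i, j] = P[j, i] = pi
    return DivergenceMatrix(ids, pd.DataFrame(K, index=ids, columns=ids),
                            pd.DataFrame(P, index=ids, columns=ids), level)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(matrix: DivergenceMatrix | pd.DataFrame,
            use: str = "per_site") -> str:
    """Neighbor-joining tree from a divergence matrix, as Newick text.

    Deterministic: ties in the Q criterion resolve to the earliest pair in
    taxon order.  Negative branch lengths are clamped to zero with a
    warning.  Requires a symmetric matrix over at least 3 taxa.
    """
    import logging

    if isinstance(matrix, DivergenceMatrix):
        df = matrix.per_site if use == "per_site" else matrix.k
    else:
        df = matrix
    ids = list(df.index)
    D = df.to_numpy(dtype=float)
    if len(ids) < 3:
        raise InputError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-9):
        raise InputError("non-symmetric matrix")

    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    labels = [_escape(t) for t in ids]
    active = list(range(len(ids)))
    dist = {(i, j): D[i, j] for i in range(len(ids)) for j in range(len(ids))}
    frags = {i: labels[i] for i in active}
    next_id = len(ids)

    def d(i, j):
        return dist[(i, j)] if i <= j else dist[(j, i)]

    while len(active) > 3:
        n = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                i, j = active[ii], active[jj]
                q = (n - 2) * d(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li_raw = 0.5 * d(i, j) + (r[i] - r[j]) / (2 * (n - 2))
        li = clamp(li_raw)
        lj = clamp(d(i, j) - li_raw)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dist[(min(u, k), max(u, k))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        dist[(u, u)] = 0.0
        frags[u] = f"({frags[i]}:{li:.8g},{frags[j]}:{lj:.8g})"
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = clamp(0.5 * (d(i, j) + d(i, k) - d(j, k)))
    lj = clamp(0.5 * (d(i, j) + d(j, k) - d(i, k)))
    lk = clamp(0.5 * (d(i, k) + d(j, k) - d(i, j)))
    if clamped:
        logging.getLogger("mitocomp").warning(
            "negative branch length(s) clamped to 0")
    return f"({frags[i]}:{li:.8g},{frags[j]}:{lj:.8g},{frags[k]}:{lk:.8g});"


def _escape(taxon: str) -> str:
    if any(c in taxon for c in " ()[]:;,'"):
        return "'" + taxon.replace("'", "''") + "'"
    return taxon
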