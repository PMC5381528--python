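"""Cross-species comparison of edited orthologs.

Given an ortholog-pair table with protein sequences, this module asks
(i) which pairs have both members edited under an editing-fraction and
amino-acid-change filter, and (ii) for pairs carrying the same
amino-acid substitution, whether the edited residues sit at orthologous
positions of a global protein alignment.

The aligner is an affine-gap Needleman–Wunsch (Gotoh) with a fixed,
deterministic tie-break (diagonal over gap-in-a over gap-in-b) so
position mapping is reproducible.  Defaults: BLOSUM62, gap open −10 for
the first gap residue, −1 for each extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentScoring",
    "Alignment",
    "OrthologPair",
    "SharedEditingReport",
    "global_align",
    "map_aligned_position",
    "shared_editing",
]

_NEG_INF = float("-inf")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X")


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix plus affine gap penalties.

    A gap of length k costs ``gap_open + (k-1) * gap_extend`` (the
    opening penalty pays for the first gapped residue).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0
    match: Optional[float] = None  # with mismatch, overrides the matrix
    mismatch: Optional[float] = None

    def score(self, a: str, b: str) -> float:
        if self.match is not None and self.mismatch is not None:
            return self.match if a == b else self.mismatch
        return float(_load_matrix(self.matrix_name)[a, b])


_MATRIX_CACHE: dict[str, object] = {}


def _load_matrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


@dataclass
class Alignment:
    """A global alignment: gapped strings plus the optimal score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class OrthologPair:
    """One reciprocal-best ortholog pair with its protein sequences."""

    gene_id_a: str
    gene_id_b: str
    protein_a: str
    protein_b: str

    def __post_init__(self) -> None:
        for name, prot in (("protein_a", self.protein_a), ("protein_b", self.protein_b)):
            if not prot:
                raise ValueError(f"{name} is empty")
            if not set(prot) <= AA_ALPHABET:
                bad = sorted(set(prot) - AA_ALPHABET)
                raise ValueError(f"{name} has invalid residues {bad}")


def global_align(a: str, b: str, scoring: AlignmentScoring = AlignmentScoring()) -> Alignment:
    """Optimal global alignment of two protein sequences (Gotoh).

    Ties are broken deterministically: diagonal (match/mismatch) is
    preferred over a gap in ``a`` (b-residue against ``-``), which is
    preferred over a gap in ``b``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    for name, seq in (("a", a), ("b", b)):
        if not set(seq) <= AA_ALPHABET:
            raise ValueError(f"sequence {name} has invalid residues")
    n, m = len(a), len(b)
    go, ge = scoring.gap_open, scoring.gap_extend
    # M: a[i] aligned to b[j]; Ia: gap in a at the end; Ib: gap in b
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ia = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ib = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        Ia[0][j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        Ib[i][0] = go + ge * (i - 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = scoring.score(ai, b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], Ia[i - 1][j - 1], Ib[i - 1][j - 1]) + s
            Ia[i][j] = max(M[i][j - 1] + go, Ia[i][j - 1] + ge, Ib[i][j - 1] + go)
            Ib[i][j] = max(M[i - 1][j] + go, Ia[i - 1][j] + go, Ib[i - 1][j] + ge)
    # traceback, precedence M > Ia > Ib at every tie
    i, j = n, m
    final_scores = {"M": M[n][m], "Ia": Ia[n][m], "Ib": Ib[n][m]}
    state = "M"
    best = max(final_scores.values())
    for st in ("M", "Ia", "Ib"):
        if final_scores[st] == best:
            state = st
            break
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = scoring.score(a[i - 1], b[j - 1])
            target = M[i][j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for st, val in (("M", M[i][j]), ("Ia", Ia[i][j]), ("Ib", Ib[i][j])):
                if val == target:
                    state = st
                    break
        elif state == "Ia":
            out_a.append("-")
            out_b.append(b[j - 1])
            target = Ia[i][j]
            j -= 1
            options = (("M", M[i][j] + go), ("Ia", Ia[i][j] + ge), ("Ib", Ib[i][j] + go))
            if j == 0 and i == 0:
                break
            if j == 0:
                state = "Ia"
                continue
            for st, val in options:
                if val == target:
                    state = st
                    break
        else:  # Ib
            out_a.append(a[i - 1])
            out_b.append("-")
            target = Ib[i][j]
            i -= 1
            if i == 0 and j == 0:
                break
            if i == 0:
                state = "Ib"
                continue
            options = (("M", M[i][j] + go), ("Ia", Ia[i][j] + go), ("Ib", Ib[i][j] + ge))
            for st, val in options:
                if val == target:
                    state = st
                    break
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)), best)


def map_aligned_position(alignment: Alignment, pos_a: int) -> int | str:
    """Residue of b aligned to residue ``pos_a`` of a, or ``"gap"``.

    Positions are 1-based residue indices in the ungapped sequences.
    """
    n_a = sum(1 for c in alignment.aligned_a if c != "-")
    if not 1 <= pos_a <= n_a:
        raise ValueError(f"pos_a {pos_a} outside sequence of length {n_a}")
    count_a = count_b = 0
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if cb != "-":
            count_b += 1
        if ca != "-":
            count_a += 1
            if count_a == pos_a:
                return count_b if cb != "-" else "gap"
    raise AssertionError("unreachable")


@dataclass
class SharedEditingReport:
    """Outcome of the two-species edited-ortholog comparison."""

    n_edited_genes_a: int
    n_edited_genes_b: int
    n_sites_a: int
    n_sites_b: int
    pairs_both_edited: list[tuple[str, str]] = field(default_factory=list)
    shared_aa_changes: list[dict] = field(default_factory=list)
    n_positionally_orthologous: int = 0
    unpaired_genes_a: list[str] = field(default_factory=list)
    unpaired_genes_b: list[str] = field(default_factory=list)


def _eligible_sites(sites: Sequence, min_edit_fraction: float, aa_changing_only: bool):
    out = []
    for s in sites:
        cons = getattr(s, "consequence", None)
        if cons is None or cons.region != "cds" or cons.category is None:
            continue
        if aa_changing_only and not cons.changes_product:
            continue
        if s.pooled_fraction() < min_edit_fraction:
            continue
        out.append(s)
    return out


def shared_editing(
    pairs: Sequence[OrthologPair],
    sites_a: Sequence,
    sites_b: Sequence,
    min_edit_fraction: float = 0.10,
    aa_changing_only: bool = True,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> SharedEditingReport:
    """Compare edited orthologs between two species.

    Sites must carry consequences and per-sample evidence; the editing
    fraction is pooled over the site's replicate samples.  For ortholog
    pairs where both genes pass the filters, site pairs with the same
    amino-acid substitution are checked for positional orthology under
    the global protein alignment.
    """
    el_a = _eligible_sites(sites_a, min_edit_fraction, aa_changing_only)
    el_b = _eligible_sites(sites_b, min_edit_fraction, aa_changing_only)
    genes_a = {s.gene_id for s in el_a}
    genes_b = {s.gene_id for s in el_b}
    pair_by_a: Mapping[str, OrthologPair] = {p.gene_id_a: p for p in pairs}
    pair_by_b: Mapping[str, OrthologPair] = {p.gene_id_b: p for p in pairs}
    report = SharedEditingReport(
        n_edited_genes_a=len(genes_a),
        n_edited_genes_b=len(genes_b),
        n_sites_a=len(el_a),
        n_sites_b=len(el_b),
        unpaired_genes_a=sorted(genes_a - set(pair_by_a)),
        unpaired_genes_b=sorted(genes_b - set(pair_by_b)),
    )
    sites_by_gene_a: dict[str, list] = {}
    for s in el_a:
        sites_by_gene_a.setdefault(s.gene_id, []).append(s)
    sites_by_gene_b: dict[str, list] = {}
    for s in el_b:
        sites_by_gene_b.setdefault(s.gene_id, []).append(s)
    for p in pairs:
        if p.gene_id_a not in genes_a or p.gene_id_b not in genes_b:
            continue
        report.pairs_both_edited.append((p.gene_id_a, p.gene_id_b))
        aln: Alignment | None = None
        for sa in sites_by_gene_a[p.gene_id_a]:
            for sb in sites_by_gene_b[p.gene_id_b]:
                ca, cb = sa.consequence, sb.consequence
                if (ca.ref_aa, ca.alt_aa) != (cb.ref_aa, cb.alt_aa):
                    continue
                if aln is None:
                    aln = global_align(p.protein_a, p.protein_b, scoring)
                mapped = map_aligned_position(aln, ca.codon_index)
                orthologous = mapped == cb.codon_index
                report.shared_aa_changes.append(
                    {
                        "gene_a": p.gene_id_a,
                        "gene_b": p.gene_id_b,
                        "pos_a": ca.codon_index,
                        "pos_b": cb.codon_index,
                        "aa_change": f"{ca.ref_aa}>{ca.alt_aa}",
                        "mapped_pos_b": mapped,
                        "positionally_orthologous": orthologous,
                    }
                )
                if orthologous:
                    report.n_positionally_orthologous += 1
    return report


def read_ortholog_pairs(
    path, proteins_a: Mapping[str, str], proteins_b: Mapping[str, str]
) -> list[OrthologPair]:
    """Read a 2-column TSV (gene_id_a, gene_id_b) and attach proteins."""
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and parts[0] == "gene_id_a":
                continue
            ga, gb = parts[0], parts[1]
            pairs.append(OrthologPair(ga, gb, proteins_a[ga], proteins_b[gb]))
    return pairs
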