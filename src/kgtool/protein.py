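"""Protein–protein similarity providers, S(p1, p2).

Two interchangeable providers feed the gene-pair score:

* :class:`AlignmentProvider` — global pairwise alignment of the two
  protein sequences (affine gaps, configurable substitution matrix) with
  the score reported as percent identity over the full alignment length,
  gap columns included. Always on a 0–100 scale.
* :class:`TableProvider` — a lookup of externally computed similarity
  scores from a TSV (``protein_a  protein_b  score``), keyed by unordered
  pair. This lets published or tool-specific similarity values (BLAST,
  DIAMOND, curated tables) be injected verbatim.

A pair missing from a table raises :class:`~kgtool.errors.UnknownPairError`
so callers can mark the gene pair unscorable instead of treating it as
zero similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import KGError, UnknownPairError

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_RESIDUES = STANDARD_RESIDUES | frozenset("XBZU")


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence in one-letter code (stored uppercase)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise KGError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinSequence]:
    """Read protein sequences from FASTA, uppercasing residues.

    The record id is the token before the first whitespace in the header.
    Duplicate ids are an error; in strict mode so is any residue outside
    the 20 standard amino acids plus X/B/Z/U.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise KGError(f"{path}: no FASTA records found")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise KGError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        bad = set(residues) - EXTENDED_RESIDUES
        if bad and strict:
            raise KGError(f"{path}: illegal residues {sorted(bad)} in {rec.id!r}")
        out.append(ProteinSequence(rec.id, residues))
    return out


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment parameters.

    ``matrix`` names a substitution matrix (e.g. ``BLOSUM62``); set it to
    ``None`` to score with plain ``match``/``mismatch`` values (useful for
    nucleotide-like alphabets). Gap penalties are positive magnitudes in
    the affine convention: a gap of length L costs
    ``gap_open + gap_extend * (L - 1)``. ``denominator`` selects the
    percent-identity denominator: the full alignment length including gap
    columns (default) or the shorter sequence length.
    """

    matrix: str | None = "BLOSUM62"
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    denominator: str = "alignment"  # "alignment" | "shorter"

    def make_aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        if self.matrix is not None:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        else:
            aligner.match_score = self.match
            aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


def align_percent_identity(
    a: ProteinSequence, b: ProteinSequence, params: AlignmentParams | None = None
) -> float:
    """Percent identity (0–100) from an optimal global alignment.

    The alignment maximizes the substitution-matrix score under affine gap
    penalties; identity is then counted over the aligned columns. When
    several alignments attain the optimal score the aligner's first
    traceback is used, which is deterministic for fixed parameters.
    """
    params = params or AlignmentParams()
    aligner = params.make_aligner()
    alignment = next(iter(aligner.align(a.residues, b.residues)))
    s1, s2 = str(alignment[0]), str(alignment[1])
    identical = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    if params.denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        denom = len(s1)
    return 100.0 * identical / denom


class SimilarityProvider:
    """Interface: a symmetric, finite, non-negative pair score."""

    def score(self, p1: str, p2: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass
class AlignmentProvider(SimilarityProvider):
    """Score protein pairs by aligning their sequences."""

    sequences: dict[str, ProteinSequence]
    params: AlignmentParams = field(default_factory=AlignmentParams)

    @classmethod
    def from_fasta(
        cls, path: str | Path, params: AlignmentParams | None = None, strict: bool = True
    ) -> "AlignmentProvider":
        seqs = read_fasta(path, strict=strict)
        return cls({s.id: s for s in seqs}, params or AlignmentParams())

    def score(self, p1: str, p2: str) -> float:
        try:
            a, b = self.sequences[p1], self.sequences[p2]
        except KeyError as exc:
            raise UnknownPairError((p1, p2)) from exc
        # align in a canonical order so score(a,b) == score(b,a) exactly
        if a.id > b.id:
            a, b = b, a
        return align_percent_identity(a, b, self.params)


class TableProvider(SimilarityProvider):
    """Score protein pairs from a precomputed similarity table."""

    def __init__(self, entries: dict[tuple[str, str], float] | None = None) -> None:
        self._entries: dict[frozenset[str] | tuple[str, str], float] = {}
        for (p1, p2), s in (entries or {}).items():
            self.add(p1, p2, s)

    @staticmethod
    def _key(p1: str, p2: str):
        return frozenset((p1, p2)) if p1 != p2 else (p1, p2)

    def add(self, p1: str, p2: str, score: float) -> None:
        score = float(score)
        if score < 0:
            raise KGError(f"similarity score must be >= 0, got {score}")
        self._entries[self._key(p1, p2)] = score

    def score(self, p1: str, p2: str) -> float:
        try:
            return self._entries[self._key(p1, p2)]
        except KeyError:
            raise UnknownPairError((p1, p2)) from None

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TableProvider":
        """Read ``protein_a<TAB>protein_b<TAB>score`` rows (optional header)."""
        table = cls()
        with Path(path).open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 3:
                    raise KGError(f"{path} line {lineno}: expected 3 columns")
                if lineno == 1 and cols[2] in {"score", "similarity"}:
                    continue
                try:
                    table.add(cols[0], cols[1], float(cols[2]))
                except ValueError as exc:
                    raise KGError(f"{path} line {lineno}: bad score {cols[2]!r}") from exc
        return table

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("protein_a\tprotein_b\tscore\n")
            rows = []
            for key, s in self._entries.items():
                pair = sorted(key) if isinstance(key, frozenset) else list(key)[:2]
                if len(pair) == 1:
                    pair = pair * 2
                rows.append((pair[0], pair[1], s))
            for p1, p2, s in sorted(rows):
                fh.write(f"{p1}\t{p2}\t{s:.6g}\n")


def all_vs_all_table(
    sequences: list[ProteinSequence], params: AlignmentParams | None = None
) -> TableProvider:
    """Align every unordered pair (self-pairs included) into a table."""
    table = TableProvider()
    params = params or AlignmentParams()
    for i, a in enumerate(sequences):
        for b in sequences[i:]:
            table.add(a.id, b.id, align_percent_identity(a, b, params))
    return table
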