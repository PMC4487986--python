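"""Local protein alignment and alignment statistics.

A desk-scale stand-in for a blastp search: exact Smith-Waterman affine-gap
local alignment (no heuristic seeding) scored with a substitution matrix,
plus Karlin-Altschul significance. Alignment itself is delegated to
Bio.Align.PairwiseAligner in local mode; this module adds the hit model
(coverage, identity, positives, E-value) that the reciprocal-best-hit
engine consumes, and an adapter for externally produced tabular hits so a
real blastp run can substitute for the internal aligner.

E-values use fixed gapped Karlin-Altschul constants (lambda = 0.267,
K = 0.041 for BLOSUM62 with gap open 11 / extend 1) and the raw search
space m*n with no edge-effect length adjustment. That is a documented
simplification: E-values here order and threshold hits the same way blastp
does, but are not numerically identical to blastp output.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from ._util import ConfigError, InputError

#: The 20 standard residues plus X (unknown); X scores 0 against everything.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_RESIDUE_RE = re.compile(f"^[{ALPHABET}]+$")

#: Gapped Karlin-Altschul constants for BLOSUM62, open 11 / extend 1.
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1

_matrix_cache: dict[str, substitution_matrices.Array] = {}


def get_matrix(name: str = DEFAULT_MATRIX) -> substitution_matrices.Array:
    """Load a substitution matrix with the X row/column zeroed."""
    if name not in _matrix_cache:
        try:
            matrix = substitution_matrices.load(name)
        except FileNotFoundError as exc:
            raise ConfigError(f"unknown substitution matrix {name!r}") from exc
        matrix = matrix.copy()
        if "X" in matrix.alphabet:
            for letter in matrix.alphabet:
                matrix["X", letter] = 0.0
                matrix[letter, "X"] = 0.0
        _matrix_cache[name] = matrix
    return _matrix_cache[name]


@dataclass(frozen=True)
class ProteinEntry:
    """One gene's canonical protein sequence in one species."""

    gene_id: str
    species: str
    sequence: str
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"protein {self.gene_id}: empty sequence")
        if not _RESIDUE_RE.match(self.sequence):
            bad = sorted(set(self.sequence) - set(ALPHABET))
            raise InputError(
                f"protein {self.gene_id}: invalid residue(s) {bad}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """A scored local alignment between two proteins.

    Spans are 1-based closed residue intervals on the full sequences;
    coverage is span length over full sequence length. ``positives`` counts
    aligned (gap-free) columns whose substitution score is positive, over
    all gap-free columns — the conventional blastp "similarity".
    """

    query_gene: str
    subject_gene: str
    raw_score: float
    query_length: int
    subject_length: int
    identity_fraction: float = 0.0
    positives_fraction: float = 0.0
    query_coverage: float = 0.0
    subject_coverage: float = 0.0
    aligned_span_query: tuple[int, int] | None = None
    aligned_span_subject: tuple[int, int] | None = None
    bit_score: float | None = None
    evalue: float | None = None

    @property
    def is_empty(self) -> bool:
        """True when no positively scoring local alignment exists."""
        return self.raw_score <= 0

    def swapped(self) -> "AlignmentHit":
        """The same alignment viewed from the subject's side."""
        return AlignmentHit(
            query_gene=self.subject_gene,
            subject_gene=self.query_gene,
            raw_score=self.raw_score,
            query_length=self.subject_length,
            subject_length=self.query_length,
            identity_fraction=self.identity_fraction,
            positives_fraction=self.positives_fraction,
            query_coverage=self.subject_coverage,
            subject_coverage=self.query_coverage,
            aligned_span_query=self.aligned_span_subject,
            aligned_span_subject=self.aligned_span_query,
            bit_score=self.bit_score,
            evalue=self.evalue,
        )


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    if gap_open <= 0 or gap_extend <= 0:
        raise ConfigError("gap penalties must be positive")
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = get_matrix(matrix_name)
    # NCBI convention: a gap of length k costs gap_open + k*gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    query: ProteinEntry,
    subject: ProteinEntry,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentHit:
    """Optimal Smith-Waterman affine-gap local alignment of two proteins."""
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(query.sequence, subject.sequence)
    if alignments.score <= 0 or len(alignments) == 0:
        return AlignmentHit(
            query_gene=query.gene_id,
            subject_gene=subject.gene_id,
            raw_score=0.0,
            query_length=len(query),
            subject_length=len(subject),
        )
    return _hit_from_alignment(query, subject, alignments[0], get_matrix(matrix))


def _hit_from_alignment(query, subject, alignment, matrix) -> AlignmentHit:
    blocks_q, blocks_s = alignment.aligned
    identities = 0
    positives = 0
    columns = 0
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        for a, b in zip(query.sequence[qs:qe], subject.sequence[ss:se]):
            columns += 1
            if a == b:
                identities += 1
            if matrix[a, b] > 0:
                positives += 1
    q_span = (int(blocks_q[0][0]) + 1, int(blocks_q[-1][1]))
    s_span = (int(blocks_s[0][0]) + 1, int(blocks_s[-1][1]))
    return AlignmentHit(
        query_gene=query.gene_id,
        subject_gene=subject.gene_id,
        raw_score=float(alignment.score),
        query_length=len(query),
        subject_length=len(subject),
        identity_fraction=identities / columns if columns else 0.0,
        positives_fraction=positives / columns if columns else 0.0,
        query_coverage=(q_span[1] - q_span[0] + 1) / len(query),
        subject_coverage=(s_span[1] - s_span[0] + 1) / len(subject),
        aligned_span_query=q_span,
        aligned_span_subject=s_span,
    )


def raw_local_score(
    query: str,
    subject: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Score-only Smith-Waterman (no traceback); faster for all-vs-all scans."""
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    return float(aligner.score(query, subject))


def significance(
    hit: AlignmentHit,
    query_len: int | None = None,
    subject_db_len: int | None = None,
    lam: float = GAPPED_LAMBDA,
    K: float = GAPPED_K,
) -> AlignmentHit:
    """Attach a bit score and E-value to a hit.

    bit = (lambda*S - ln K) / ln 2;  E = K * m * n * exp(-lambda*S)
    with m the query length and n the searched database length in residues.
    """
    if lam <= 0 or K <= 0:
        raise ConfigError("Karlin-Altschul parameters must be positive")
    m = hit.query_length if query_len is None else query_len
    n = hit.subject_length if subject_db_len is None else subject_db_len
    if m <= 0 or n <= 0:
        raise InputError("sequence/database lengths must be positive")
    bit = (lam * hit.raw_score - math.log(K)) / math.log(2)
    evalue = K * m * n * math.exp(-lam * hit.raw_score)
    return replace(hit, bit_score=bit, evalue=evalue)


# ---------------------------------------------------------------------------
# FASTA and tabular-hit I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, species: str | None = None) -> list[ProteinEntry]:
    """Read proteins from FASTA. Headers are "species|gene_id[|accession]";
    a bare gene id is accepted when ``species`` is given explicitly."""
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) >= 2:
            sp, gene = parts[0], parts[1]
            accession = parts[2] if len(parts) > 2 else ""
        elif species is not None:
            sp, gene, accession = species, parts[0], ""
        else:
            raise InputError(
                f"FASTA header {record.id!r} lacks a species prefix"
            )
        entries.append(
            ProteinEntry(
                gene_id=gene,
                species=sp,
                sequence=str(record.seq).upper(),
                accession=accession,
            )
        )
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            header = f"{e.species}|{e.gene_id}"
            if e.accession:
                header += f"|{e.accession}"
            fh.write(f">{header}\n")
            seq = e.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_tabular_hits(
    path: str | Path,
    query_lengths: Mapping[str, int],
    subject_lengths: Mapping[str, int],
) -> list[AlignmentHit]:
    """Adapt 12-column blastp tabular output (outfmt 6) to AlignmentHit.

    Columns: query, subject, %identity, length, mismatches, gapopens,
    qstart, qend, sstart, send, evalue, bitscore. The tabular dialect does
    not carry positives, so positives_fraction is set equal to the identity
    fraction; raw score is back-computed from the bit score.
    """
    hits = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise InputError(
                    f"{path}:{line_no}: expected 12 tab-separated columns"
                )
            (q, s, pident, _length, _mm, _go, qs, qe, ss, se, ev, bits) = fields
            if q not in query_lengths:
                raise InputError(f"{path}:{line_no}: unknown query {q!r}")
            if s not in subject_lengths:
                raise InputError(f"{path}:{line_no}: unknown subject {s!r}")
            qlen, slen = query_lengths[q], subject_lengths[s]
            bit = float(bits)
            raw = (bit * math.log(2) + math.log(GAPPED_K)) / GAPPED_LAMBDA
            q_span = (int(qs), int(qe))
            s_span = tuple(sorted((int(ss), int(se))))
            ident = float(pident) / 100.0
            hits.append(
                AlignmentHit(
                    query_gene=q,
                    subject_gene=s,
                    raw_score=raw,
                    query_length=qlen,
                    subject_length=slen,
                    identity_fraction=ident,
                    positives_fraction=ident,
                    query_coverage=(q_span[1] - q_span[0] + 1) / qlen,
                    subject_coverage=(s_span[1] - s_span[0] + 1) / slen,
                    aligned_span_query=q_span,
                    aligned_span_subject=s_span,
                    bit_score=bit,
                    evalue=float(ev),
                )
            )
    return hits
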