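"""Duf421-family homolog classification and per-species census.

YetF-like proteins carry only a Duf421-like domain (~210-253 residues);
2Duf carries Duf421 plus Duf1657 (~285-290 residues), so sequence
length alone separates the two classes.  This module aligns candidate
proteins globally against reference prototypes to obtain percent
identity and query coverage, applies the hit filter (E-value < 1e-30
where an external hit table supplies E-values, query coverage > 85%),
classifies by length, and tabulates per-species counts and best hits.

Alignment uses an affine-gap global aligner (BLOSUM62, gap open 10,
extend 0.5 by default).  Percent identity excludes terminal-gap columns
so that length-mismatched Duf421 vs 2Duf comparisons are not deflated
mechanically by the extra Duf1657 domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinRecord",
    "HomologCall",
    "AlignmentScoring",
    "AlignmentResult",
    "global_align",
    "classify_length",
    "call_homologs",
    "census",
    "read_fasta",
    "write_fasta",
    "DEFAULT_RANGES",
]

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

# length windows from the family survey: YetF-like spans 210-253 aa
# across Bacilli and Clostridia; 2Duf-like 285-290 aa
DEFAULT_RANGES = {"yetf": (210, 253), "duf2": (285, 290)}


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        return "X" in self.sequence.upper()


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution table plus affine gap penalties (penalties positive).

    ``matrix`` is a substitution-matrix name ("BLOSUM62", ...) or None,
    in which case ``match``/``mismatch`` scores are used.  Setting
    ``gap_extend == gap_open`` gives linear gap costs.
    """

    matrix: str | None = "BLOSUM62"
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class AlignmentResult:
    score: float
    aligned_query: str
    aligned_target: str
    percent_identity: float
    query_coverage: float


@dataclass
class HomologCall:
    protein_id: str
    species: str
    length: int
    query: str  # "YetF" or "2Duf" — best-scoring reference
    percent_identity: float
    query_coverage: float
    homolog_class: str  # YetF-like | 2Duf-like | unclassified
    evalue: float | None = None
    passes_filter: bool = False


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if scoring.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    else:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = -abs(scoring.gap_open)
    aligner.extend_gap_score = -abs(scoring.gap_extend)
    return aligner


def global_align(
    query: str, target: str, scoring: AlignmentScoring | None = None
) -> AlignmentResult:
    """Optimal global alignment with percent identity and query coverage.

    Identity = identical columns / aligned columns, excluding columns
    inside a terminal gap of either sequence; coverage = query residues
    in non-terminal-gap columns / query length.  The traceback is
    biopython's deterministic first optimal alignment.
    """
    if not query or not target:
        raise ValueError("sequences must be nonempty")
    for seq, name in ((query, "query"), (target, "target")):
        bad = set(seq.upper()) - VALID_RESIDUES
        if bad:
            raise ValueError(f"{name} has invalid residues {sorted(bad)}")
    scoring = scoring or AlignmentScoring()
    aligner = _make_aligner(scoring)
    aln = aligner.align(query.upper(), target.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])

    def core(s: str) -> tuple[int, int]:
        return len(s) - len(s.lstrip("-")), len(s.rstrip("-"))

    a0, a1 = core(s1)
    b0, b1 = core(s2)
    start, end = max(a0, b0), min(a1, b1)
    n_cols = max(end - start, 0)
    if n_cols == 0:
        return AlignmentResult(float(aln.score), s1, s2, 0.0, 0.0)
    ident = sum(
        1 for i in range(start, end) if s1[i] == s2[i] and s1[i] != "-"
    )
    q_res = sum(1 for i in range(start, end) if s1[i] != "-")
    return AlignmentResult(
        score=float(aln.score),
        aligned_query=s1,
        aligned_target=s2,
        percent_identity=100.0 * ident / n_cols,
        query_coverage=100.0 * q_res / len(query),
    )


def classify_length(
    length: int, ranges: dict[str, tuple[int, int]] | None = None
) -> str:
    """Classify by residue count: YetF-like, 2Duf-like or unclassified.

    Ranges are inclusive and must not overlap (they partition lengths).
    """
    ranges = ranges or DEFAULT_RANGES
    y_lo, y_hi = ranges["yetf"]
    d_lo, d_hi = ranges["duf2"]
    if y_lo <= d_hi and d_lo <= y_hi:
        raise ValueError("yetf and duf2 length ranges overlap")
    if length <= 0:
        raise ValueError("length must be > 0")
    if y_lo <= length <= y_hi:
        return "YetF-like"
    if d_lo <= length <= d_hi:
        return "2Duf-like"
    return "unclassified"


def call_homologs(
    records: list[ProteinRecord],
    queries: dict[str, str] | None = None,
    scoring: AlignmentScoring | None = None,
    ranges: dict[str, tuple[int, int]] | None = None,
) -> list[HomologCall]:
    """Align each record to the reference queries and classify it.

    Each record is aligned globally to every query sequence; the
    best-scoring query provides the reported identity and coverage.
    """
    if queries is None:
        from .synth import DUF2_PROTOTYPE, YETF_PROTOTYPE

        queries = {"YetF": YETF_PROTOTYPE, "2Duf": DUF2_PROTOTYPE}
    calls = []
    for rec in records:
        best_label, best_res = None, None
        for label, qseq in queries.items():
            res = global_align(qseq, rec.sequence, scoring)
            if best_res is None or res.score > best_res.score:
                best_label, best_res = label, res
        calls.append(
            HomologCall(
                protein_id=rec.id,
                species=rec.species,
                length=rec.length,
                query=best_label,
                percent_identity=best_res.percent_identity,
                query_coverage=best_res.query_coverage,
                homolog_class=classify_length(rec.length, ranges),
            )
        )
    return calls


def census(
    calls: list[HomologCall],
    hit_table: pd.DataFrame | None = None,
    min_coverage: float = 85.0,
    max_evalue: float = 1e-30,
    min_identity: float = 0.0,
    best_hit_rule: str = "most_significant",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species homolog counts and best hits.

    ``hit_table`` (columns: protein_id, evalue, optionally coverage)
    supplies externally computed E-values; with it, a call passes the
    filter when ``evalue < max_evalue`` and coverage > ``min_coverage``.
    Without E-values the coverage and ``min_identity`` thresholds apply.
    The best hit per (species, query) is the passing call with the
    smallest E-value (``best_hit_rule="literal_max"`` selects the
    numerically largest instead), or the highest identity when no
    E-values exist; ties break by identity then id.

    Returns ``(census_table, best_hits)``: the census table counts
    passing YetF-like / 2Duf-like calls per species plus records that
    are unclassified or filtered out.
    """
    if best_hit_rule not in ("most_significant", "literal_max"):
        raise ValueError("best_hit_rule must be 'most_significant' or 'literal_max'")
    evalues: dict[str, float] = {}
    coverages: dict[str, float] = {}
    if hit_table is not None:
        for _, row in hit_table.iterrows():
            evalues[str(row["protein_id"])] = float(row["evalue"])
            if "coverage" in hit_table.columns and pd.notna(row.get("coverage")):
                coverages[str(row["protein_id"])] = float(row["coverage"])

    for c in calls:
        cov = coverages.get(c.protein_id, c.query_coverage)
        if c.protein_id in evalues:
            c.evalue = evalues[c.protein_id]
            c.passes_filter = c.evalue < max_evalue and cov > min_coverage
        else:
            c.passes_filter = cov > min_coverage and c.percent_identity >= min_identity

    species = sorted({c.species for c in calls})
    rows = []
    for sp in species:
        sp_calls = [c for c in calls if c.species == sp]
        passing = [c for c in sp_calls if c.passes_filter]
        n_yetf = sum(1 for c in passing if c.homolog_class == "YetF-like")
        n_duf2 = sum(1 for c in passing if c.homolog_class == "2Duf-like")
        rows.append(
            {
                "species": sp,
                "n_yetf_like": n_yetf,
                "n_2duf_like": n_duf2,
                "n_unclassified": len(sp_calls) - n_yetf - n_duf2,
            }
        )
    census_table = pd.DataFrame(rows)

    best_rows = []
    for sp in species:
        for query in sorted({c.query for c in calls}):
            group = [
                c
                for c in calls
                if c.species == sp and c.query == query and c.passes_filter
            ]
            if not group:
                continue
            if any(c.evalue is not None for c in group):
                sign = 1.0 if best_hit_rule == "most_significant" else -1.0
                key = lambda c: (
                    sign * (c.evalue if c.evalue is not None else np.inf),
                    -c.percent_identity,
                    c.protein_id,
                )
            else:
                key = lambda c: (-c.percent_identity, c.protein_id)
            best = min(group, key=key)
            best_rows.append(
                {
                    "species": sp,
                    "query": query,
                    "protein_id": best.protein_id,
                    "percent_identity": best.percent_identity,
                    "query_coverage": best.query_coverage,
                    "evalue": best.evalue,
                    "homolog_class": best.homolog_class,
                }
            )
    return census_table, pd.DataFrame(best_rows)


# ---------------------------------------------------------------------------
# FASTA I/O — record ids parsed as "species|protein_id"


def read_fasta(path: str) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        if "|" in rec.id:
            species, pid = rec.id.split("|", 1)
        else:
            species, pid = "unknown", rec.id
        records.append(ProteinRecord(id=pid, species=species, sequence=str(rec.seq)))
    return records


def write_fasta(path: str, records: list[ProteinRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.species}|{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")
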