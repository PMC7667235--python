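"""Low-copy ortholog supermatrix construction.

Stages, in pipeline order: longest-ORF selection from assembled transcripts;
per-species fragment/paralog resolution inside each orthogroup (sequences
that barely overlap in aligned coordinates are assembly fragments and are
merged, sequences that overlap substantially are paralogs and the species is
dropped from that orthogroup); orthogroup filtering on species presence,
multicopy fraction and alignment length; codon back-translation of the
protein alignments; whole-codon gap trimming; and concatenation into a
partitioned supermatrix.

Overlap between two aligned rows is the number of columns where both are
non-gap, divided by the shorter row's non-gap length. The merge threshold
defaults to 0.10 — fragments from a fragmented assembly should barely
overlap, while true paralogs align over most of their length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .io_formats import GAP, Alignment, Orthogroup, Partition, PartitionedMatrix

__all__ = [
    "OrfResult",
    "FilterConfig",
    "FilterReport",
    "Resolution",
    "TrimResult",
    "longest_orf",
    "aligned_overlap",
    "resolve_multicopy",
    "filter_orthogroups",
    "backtranslate",
    "trim_codon_columns",
    "concatenate",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfResult:
    protein: str
    cds: str  # includes the stop codon when one terminates the ORF
    frame: int  # 0..2 within the strand
    strand: str  # "+" | "-"
    start: int  # 0-based half-open, forward-strand coordinates
    end: int


def _scan_frame(seq: str, frame: int, require_start: bool):
    """ORFs in one frame of one strand: (prot_len, start, end, protein, cds).

    Coordinates are 0-based half-open within ``seq``. An ORF runs from a
    start codon (ATG mode) or the codon after the previous stop
    (stop-to-stop mode) through the next stop codon or the sequence edge;
    the stop is kept in the CDS but excluded from the translation.
    """
    orfs = []
    codon_starts = range(frame, len(seq) - 2, 3)
    open_start = None if require_start else (frame if frame + 3 <= len(seq) else None)
    for pos in codon_starts:
        codon = seq[pos : pos + 3]
        if codon in _STOPS:
            if open_start is not None and pos > open_start:
                orfs.append((open_start, pos + 3, True))
            open_start = None if require_start else pos + 3
        elif require_start and open_start is None and codon == "ATG":
            open_start = pos
    if open_start is not None:
        last = frame + 3 * ((len(seq) - frame) // 3)
        if last > open_start:
            orfs.append((open_start, last, False))
    out = []
    for s, e, has_stop in orfs:
        cds = seq[s:e]
        coding = cds[:-3] if has_stop else cds
        if not coding:
            continue
        protein = str(Seq(coding).translate())
        out.append((len(protein), s, e, protein, cds))
    return out


def longest_orf(sequence: str, require_start: bool = True) -> OrfResult:
    """Longest open reading frame over all six frames.

    ``require_start`` (default): an ORF begins at the first in-frame ATG
    after a stop (or the sequence edge) and runs to the next stop or edge.
    With ``require_start=False`` ORFs are stop-to-stop stretches. The
    longest protein wins; ties break by frame scan order (+0, +1, +2, -0,
    -1, -2) then by the 5'-most start within the frame. Coordinates are
    reported 0-based half-open on the forward strand.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in nucleotide sequence: {sorted(bad)}")
    rc = str(Seq(seq).reverse_complement())
    best = None
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            for plen, start, end, protein, cds in _scan_frame(s, frame, require_start):
                key = (plen,)  # scan order already encodes the tie-breaks
                if best is None or plen > best[0]:
                    if strand == "+":
                        fstart, fend = start, end
                    else:
                        fstart, fend = len(seq) - end, len(seq) - start
                    best = (plen, OrfResult(protein, cds, frame, strand, fstart, fend))
    if best is None:
        raise ValueError("no open reading frame of at least one codon")
    return best[1]


def _nongap_cols(row: str) -> set[int]:
    return {i for i, c in enumerate(row) if c != GAP}


def aligned_overlap(frag_a: str, frag_b: str) -> float:
    """Fraction of the shorter row's residues that sit in shared columns.

    |columns non-gap in both| / min(non-gap length a, non-gap length b).
    Symmetric; an all-gap row is an error.
    """
    ca, cb = _nongap_cols(frag_a), _nongap_cols(frag_b)
    if not ca or not cb:
        raise ValueError("cannot compute overlap for an all-gap row")
    return len(ca & cb) / min(len(ca), len(cb))


@dataclass(frozen=True)
class Resolution:
    action: str  # "single" | "merged_fragments" | "dropped_paralogs"
    row: str | None = None  # merged (or single) aligned row, None when dropped
    seq_ids: tuple[str, ...] = ()


def resolve_multicopy(rows: list[tuple[str, str]], threshold: float = 0.10) -> Resolution:
    """Merge non-overlapping fragments or drop overlapping paralogs.

    ``rows`` are (sequence id, aligned row) pairs for one species in one
    orthogroup. If every pairwise overlap is at or below ``threshold`` the
    rows are concatenated into one row (fragments ordered by first non-gap
    column; a doubly-covered column takes the residue of the earlier-
    starting fragment). Otherwise the species is dropped.
    """
    if len(rows) < 2:
        raise ValueError("resolve_multicopy needs >= 2 rows")
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            if aligned_overlap(rows[i][1], rows[j][1]) > threshold:
                return Resolution("dropped_paralogs", None, tuple(r[0] for r in rows))
    ordered = sorted(rows, key=lambda r: min(_nongap_cols(r[1])))
    width = len(ordered[0][1])
    merged = [GAP] * width
    for _, row in reversed(ordered):  # earlier-starting fragment wins ties
        for k, c in enumerate(row):
            if c != GAP:
                merged[k] = c
    return Resolution("merged_fragments", "".join(merged), tuple(r[0] for r in ordered))


@dataclass
class FilterConfig:
    """Orthogroup selection thresholds.

    ``min_species_present`` may be an absolute count or a fraction of
    ``n_species_total`` (a fraction generalizes the criterion to other
    rosters; counts are taken as ceil(fraction * total)).
    """

    n_species_total: int
    min_species_present: float = 40 / 53
    max_multi_frac: float = 0.10
    min_aln_len_aa: int = 100
    overlap_threshold: float = 0.10
    gap_threshold: float = 0.5

    @property
    def min_present_count(self) -> int:
        if self.min_species_present >= 1:
            return int(self.min_species_present)
        return math.ceil(self.min_species_present * self.n_species_total - 1e-9)


@dataclass
class FilterReport:
    """Per-orthogroup decisions plus per-species resolutions."""

    decisions: dict[str, str] = field(default_factory=dict)  # og_id -> kept|rejected
    reasons: dict[str, str] = field(default_factory=dict)  # og_id -> reason
    resolutions: dict[tuple[str, str], str] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        return [
            {"og_id": og, "decision": self.decisions[og], "reason": self.reasons[og]}
            for og in self.decisions
        ]


def _species_of_row(seq_id: str, og: Orthogroup) -> str | None:
    for sp, ids in og.members.items():
        if seq_id in ids:
            return sp
    return None


def resolve_orthogroup(og: Orthogroup, threshold: float = 0.10,
                       report: FilterReport | None = None) -> Alignment:
    """Per-species multicopy resolution applied to one orthogroup alignment.

    Returns an alignment with exactly one row per surviving species, row ids
    renamed to the species name.
    """
    if og.alignment is None:
        raise ValueError(f"orthogroup {og.og_id} has no alignment attached")
    by_species: dict[str, list[tuple[str, str]]] = {}
    for sid, row in og.alignment:
        sp = _species_of_row(sid, og) or sid
        by_species.setdefault(sp, []).append((sid, row))
    ids, rows = [], []
    for sp, sprows in by_species.items():
        if len(sprows) == 1:
            action, row = "single", sprows[0][1]
        else:
            res = resolve_multicopy(sprows, threshold)
            action, row = res.action, res.row
        if report is not None:
            report.resolutions[(og.og_id, sp)] = action
        if row is not None:
            ids.append(sp)
            rows.append(row)
    return Alignment(ids=ids, seqs=rows, alphabet=og.alignment.alphabet)


def filter_orthogroups(ogs: list[Orthogroup], config: FilterConfig
                       ) -> tuple[list[tuple[Orthogroup, Alignment]], FilterReport]:
    """Select low-copy orthogroups suitable for the supermatrix.

    Per orthogroup: resolve multicopy species first (merged fragments still
    count as present), then require presence of at least the configured
    number of species, a multicopy-species fraction (of the full roster,
    counted before resolution) at or below ``max_multi_frac``, and an
    alignment of at least ``min_aln_len_aa`` columns. The first failing rule
    is recorded.
    """
    report = FilterReport()
    kept: list[tuple[Orthogroup, Alignment]] = []
    for og in ogs:
        n_multi = len(og.multicopy_species)
        resolved = resolve_orthogroup(og, config.overlap_threshold, report)
        if len(resolved) < config.min_present_count:
            report.decisions[og.og_id] = "rejected"
            report.reasons[og.og_id] = "too_few_species"
            continue
        if n_multi / config.n_species_total > config.max_multi_frac:
            report.decisions[og.og_id] = "rejected"
            report.reasons[og.og_id] = "too_many_multicopy"
            continue
        if resolved.column_count < config.min_aln_len_aa:
            report.decisions[og.og_id] = "rejected"
            report.reasons[og.og_id] = "too_short"
            continue
        report.decisions[og.og_id] = "kept"
        report.reasons[og.og_id] = "none"
        kept.append((og, resolved))
    return kept, report


def backtranslate(protein_aln: Alignment, cds: dict[str, str]) -> Alignment:
    """Codon alignment from a protein alignment plus per-row coding sequences.

    Each residue column becomes its codon; gap columns become ``---``. A
    trailing stop codon on the CDS is stripped. The CDS must translate to
    exactly the row's ungapped residues, else the offending sequence and
    1-based residue index are reported.
    """
    ids, rows = [], []
    for sid, prow in protein_aln:
        try:
            nt = cds[sid].upper().replace("U", "T")
        except KeyError:
            raise KeyError(f"no CDS for aligned sequence {sid!r}") from None
        residues = prow.replace(GAP, "")
        if len(nt) == 3 * len(residues) + 3 and nt[-3:] in _STOPS:
            nt = nt[:-3]
        if len(nt) != 3 * len(residues):
            raise ValueError(
                f"{sid}: CDS length {len(nt)} does not match {len(residues)} aligned residues"
            )
        translated = str(Seq(nt).translate())
        for k, (res, tr) in enumerate(zip(residues, translated), start=1):
            if res != tr and res != "X" and tr != "X":
                raise ValueError(
                    f"{sid}: CDS translation mismatch at residue position {k} "
                    f"({tr!r} != aligned {res!r})"
                )
        codons = []
        pos = 0
        for c in prow:
            if c == GAP:
                codons.append(GAP * 3)
            else:
                codons.append(nt[pos : pos + 3])
                pos += 3
        ids.append(sid)
        rows.append("".join(codons))
    return Alignment(ids=ids, seqs=rows, alphabet="nucleotide")


@dataclass(frozen=True)
class TrimResult:
    alignment: Alignment
    kept_codons: tuple[int, ...]  # 0-based codon indices into the input


def trim_codon_columns(codon_aln: Alignment, gap_threshold: float = 0.5) -> TrimResult:
    """Remove gappy codon columns, whole codons at a time to preserve frame.

    A codon column is kept iff the fraction of sequences carrying a non-gap
    codon there is at least ``gap_threshold`` (boundary inclusive, so with
    threshold 0.5 a half-gapped column survives).
    """
    w = codon_aln.column_count
    if w % 3 != 0:
        raise ValueError(f"codon alignment width {w} is not a multiple of 3")
    n = len(codon_aln)
    kept = []
    for c in range(w // 3):
        non_gap = sum(
            1 for s in codon_aln.seqs if s[3 * c : 3 * c + 3] != GAP * 3
        )
        if non_gap / n >= gap_threshold:
            kept.append(c)
    rows = [
        "".join(s[3 * c : 3 * c + 3] for c in kept) for s in codon_aln.seqs
    ]
    trimmed = Alignment(ids=list(codon_aln.ids), seqs=rows,
                        descriptions=list(codon_aln.descriptions),
                        alphabet=codon_aln.alphabet)
    return TrimResult(trimmed, tuple(kept))


def concatenate(alignments: dict[str, Alignment], roster: list[str]) -> PartitionedMatrix:
    """Concatenate per-orthogroup codon alignments into a partitioned matrix.

    Orthogroups are ordered by id; a species absent from an orthogroup is
    padded with gaps across that orthogroup's columns. Row ids in each
    alignment must be species names from the roster.
    """
    order = sorted(alignments)
    for og_id in order:
        extra = set(alignments[og_id].ids) - set(roster)
        if extra:
            raise ValueError(f"{og_id}: species not in roster: {sorted(extra)}")
    parts: list[Partition] = []
    rows = {sp: [] for sp in roster}
    start = 1
    for og_id in order:
        aln = alignments[og_id]
        w = aln.column_count
        for sp in roster:
            rows[sp].append(aln.get(sp) if sp in aln else GAP * w)
        parts.append(Partition(name=og_id, start=start, end=start + w - 1,
                               datatype="DNA" if aln.alphabet == "nucleotide" else "PROT"))
        start += w
    matrix_aln = Alignment(
        ids=list(roster),
        seqs=["".join(rows[sp]) for sp in roster],
        alphabet=alignments[order[0]].alphabet if order else None,
    )
    return PartitionedMatrix(alignment=matrix_aln, partitions=parts)
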