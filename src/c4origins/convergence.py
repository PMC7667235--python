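"""Expression-based C4 gene-copy assignment and convergent-site scoring.

Gene families recruited into the C4 cycle (PEPC, NAD-ME, NADP-ME, PPDK)
typically contain several copies per species; the copy carrying the C4
function is taken to be the one with the highest transcript expression,
measured as RPKM (reads per kilobase of transcript per million reads, here
normalized by total sequenced rather than total mapped reads).

Convergence scoring compares the amino acids a C4 clade carries at a
catalog of positively-selected PEP-carboxylase positions (numbered on the
maize reference coordinate system) against the residue set observed in
independently evolved C4 grasses. A site counts as convergent for a clade
when the clade's consensus residue matches the grass C4 set AND differs
from the C3 sister consensus; a site where the C3 sister already carries
the grass residue is flagged ancestral_shared and not counted, and a clade
that is polymorphic at a site is reported as "partial" rather than counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from Bio.SeqUtils import seq3

from .io_formats import GAP, Alignment

__all__ = [
    "SiteEntry",
    "SiteCatalog",
    "CopyAssignment",
    "PositionMap",
    "ConvergenceReport",
    "load_site_catalog",
    "load_expression_table",
    "load_clade_residues",
    "rpkm",
    "assign_functional_copy",
    "map_reference_positions",
    "clade_residues",
    "score_convergence",
]

_AA3 = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
}


def rpkm(read_count: float, transcript_len_bp: float, total_reads: float) -> float:
    """Reads per kilobase of transcript per million sequenced reads."""
    if transcript_len_bp <= 0:
        raise ValueError("transcript length must be positive")
    if total_reads <= 0:
        raise ValueError("total read count must be positive")
    return read_count / ((transcript_len_bp / 1000.0) * (total_reads / 1e6))


@dataclass(frozen=True)
class CopyAssignment:
    copy: str | tuple[str, ...]  # tuple when tied at the maximum
    dominance_ratio: float  # max / second-max; inf for a single copy
    co_expression: bool  # second copy >= half the top copy
    tie: bool = False


def assign_functional_copy(rows: pd.DataFrame, rpkm_col: str = "rpkm",
                           co_expression_factor: float = 0.5) -> CopyAssignment:
    """Pick the putative C4-functional copy: the one with highest RPKM.

    ``rows`` holds one species x one gene family, with columns ``copy`` and
    an expression column. The dominance ratio is top/second expression; the
    co-expression flag fires when the runner-up reaches
    ``co_expression_factor`` of the top copy. An exact tie at the maximum
    returns all tied copies with the tie flag.
    """
    if rows.empty:
        raise ValueError("no copies to assign")
    vals = rows[[rpkm_col, "copy"]].sort_values(rpkm_col, ascending=False)
    top = vals.iloc[0]
    if len(vals) == 1:
        return CopyAssignment(str(top["copy"]), float("inf"), False)
    second = vals.iloc[1]
    if second[rpkm_col] == top[rpkm_col]:
        tied = tuple(vals.loc[vals[rpkm_col] == top[rpkm_col], "copy"].astype(str))
        return CopyAssignment(tied, 1.0, True, tie=True)
    ratio = float(top[rpkm_col]) / float(second[rpkm_col]) if second[rpkm_col] > 0 else float("inf")
    co = float(second[rpkm_col]) >= co_expression_factor * float(top[rpkm_col])
    return CopyAssignment(str(top["copy"]), ratio, co)


# ---------------------------------------------------------------------------
# Site catalog


@dataclass(frozen=True)
class SiteEntry:
    position: int  # 1-based residue index on the reference coordinate system
    c4_grass_residues: frozenset[str]  # 3-letter codes
    c3_reference_residue: str
    confidence_class: str  # "p>0.999" | "p>0.99" | "p>0.95"


@dataclass
class SiteCatalog:
    entries: list[SiteEntry]

    def __post_init__(self) -> None:
        pos = [e.position for e in self.entries]
        if len(set(pos)) != len(pos):
            raise ValueError("duplicate catalog positions")
        if pos != sorted(pos):
            raise ValueError("catalog positions must be ascending")
        for e in self.entries:
            bad = (set(e.c4_grass_residues) | {e.c3_reference_residue}) - _AA3
            if bad:
                raise ValueError(f"invalid residue codes at {e.position}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def positions(self) -> list[int]:
        return [e.position for e in self.entries]

    def entry(self, position: int) -> SiteEntry:
        for e in self.entries:
            if e.position == position:
                return e
        raise KeyError(position)


def _data_path(name: str):
    return resources.files("c4origins.data").joinpath(name)


def load_site_catalog(path=None) -> SiteCatalog:
    """Load a positively-selected-site catalog (default: the packaged PEPC
    catalog of grass positive-selection sites on maize numbering).

    Schema: TSV with columns position, confidence, c3_residue,
    c4_grass_residues (comma-separated 3-letter codes).
    """
    src = path if path is not None else _data_path("pepc_selected_sites.tsv")
    df = pd.read_csv(src, sep="\t")
    entries = [
        SiteEntry(
            position=int(r["position"]),
            c4_grass_residues=frozenset(s.strip() for s in str(r["c4_grass_residues"]).split(",")),
            c3_reference_residue=str(r["c3_residue"]).strip(),
            confidence_class=str(r["confidence"]).strip(),
        )
        for _, r in df.sort_values("position").iterrows()
    ]
    return SiteCatalog(entries)


def load_expression_table(path=None) -> pd.DataFrame:
    """Load a per-copy expression table (default: the packaged C4-cycle gene
    expression fixture). Columns: species, pathway, family, copy, rpkm.

    When raw columns (read_count, transcript_len_bp, total_reads) are
    present instead of ``rpkm``, RPKM is derived.
    """
    src = path if path is not None else _data_path("c4_gene_expression.tsv")
    df = pd.read_csv(src, sep="\t")
    if "rpkm" not in df.columns:
        df["rpkm"] = [
            rpkm(r["read_count"], r["transcript_len_bp"], r["total_reads"])
            for _, r in df.iterrows()
        ]
    return df


def load_clade_residues(path=None) -> dict[str, dict[int, tuple[str, ...]]]:
    """Load observed per-clade residues at catalog sites.

    Schema: TSV with columns clade, position, residues (comma-separated
    3-letter codes; more than one entry marks a polymorphic clade). Default
    is the packaged PEPC observation table for the two C4 Nyctaginaceae
    clades and their C3 sister consensus.
    """
    src = path if path is not None else _data_path("pepc_clade_residues.tsv")
    df = pd.read_csv(src, sep="\t")
    out: dict[str, dict[int, tuple[str, ...]]] = {}
    for _, r in df.iterrows():
        residues = tuple(s.strip() for s in str(r["residues"]).split(","))
        out.setdefault(str(r["clade"]), {})[int(r["position"])] = residues
    return out


# ---------------------------------------------------------------------------
# Coordinate mapping


@dataclass
class PositionMap:
    """Bidirectional map between alignment columns (0-based) and reference
    residue numbers (1-based over the reference's non-gap columns)."""

    col_to_pos: dict[int, int]
    pos_to_col: dict[int, int]

    def column(self, position: int) -> int:
        try:
            return self.pos_to_col[position]
        except KeyError:
            raise KeyError(f"reference position {position} beyond reference length") from None

    def position(self, column: int) -> int | None:
        return self.col_to_pos.get(column)


def map_reference_positions(alignment: Alignment, reference_id: str) -> PositionMap:
    """Residue numbering of a reference row within its alignment.

    Position k (1-based) is the alignment column holding the reference's
    k-th non-gap residue; columns where the reference is gapped map to no
    position.
    """
    try:
        ref = alignment.get(reference_id)
    except KeyError:
        raise KeyError(f"reference {reference_id!r} not in alignment") from None
    col_to_pos: dict[int, int] = {}
    pos_to_col: dict[int, int] = {}
    pos = 0
    for col, c in enumerate(ref):
        if c != GAP:
            pos += 1
            col_to_pos[col] = pos
            pos_to_col[pos] = col
    return PositionMap(col_to_pos, pos_to_col)


def clade_residues(alignment: Alignment, clades: dict[str, list[str]],
                   catalog: SiteCatalog, position_map: PositionMap
                   ) -> dict[str, dict[int, tuple[str, ...]]]:
    """Observed residue sets per clade at every catalog site.

    Returns clade -> position -> sorted tuple of 3-letter residues observed
    across the clade's members (singleton = consensus; longer = polymorphic;
    gaps are ignored).
    """
    matrix: dict[str, dict[int, tuple[str, ...]]] = {}
    for clade, members in clades.items():
        for m in members:
            if m not in alignment:
                raise KeyError(f"clade {clade!r} member {m!r} not in alignment")
        sites: dict[int, tuple[str, ...]] = {}
        for entry in catalog:
            col = position_map.column(entry.position)
            residues = set()
            for m in members:
                c = alignment.get(m)[col]
                if c != GAP:
                    residues.add(seq3(c))
            sites[entry.position] = tuple(sorted(residues))
        matrix[clade] = sites
    return matrix


# ---------------------------------------------------------------------------
# Convergence scoring


@dataclass
class ConvergenceReport:
    sites: pd.DataFrame  # columns: clade, position, residues, flags...
    counts: pd.DataFrame  # per clade: n_convergent, n_partial, n_catalog_sites, fraction

    def n_convergent(self, clade: str) -> int:
        return int(self.counts.set_index("clade").loc[clade, "n_convergent"])

    def fraction(self, clade: str) -> float:
        return float(self.counts.set_index("clade").loc[clade, "fraction"])


def score_convergence(matrix: dict[str, dict[int, tuple[str, ...]]],
                      catalog: SiteCatalog, c3_sister_clade: str,
                      mode: str = "consensus",
                      denominator: int | None = None) -> ConvergenceReport:
    """Score convergent amino-acid substitutions per C4 clade.

    ``matrix`` is clade -> position -> residue tuple (as from
    :func:`clade_residues` or :func:`load_clade_residues`) and must include
    the designated C3 sister clade. A site is convergent for a clade when
    its consensus residue is in the grass C4 set and differs from the C3
    sister's residues; polymorphic clades where some member matches count
    as partial (excluded from n_convergent in ``consensus`` mode, included
    in ``any_member`` mode). ``denominator`` overrides the fraction's
    denominator (default: the number of catalog sites).
    """
    if mode not in ("consensus", "any_member"):
        raise ValueError(f"unknown mode {mode!r}")
    if c3_sister_clade not in matrix:
        raise KeyError(f"C3 sister clade {c3_sister_clade!r} missing from matrix")
    sister = matrix[c3_sister_clade]
    denom = denominator if denominator is not None else len(catalog)
    site_rows = []
    count_rows = []
    for clade, sites in matrix.items():
        if clade == c3_sister_clade:
            continue
        n_conv = n_partial = 0
        for entry in catalog:
            obs = sites.get(entry.position, ())
            sis = set(sister.get(entry.position, ()))
            grass = entry.c4_grass_residues
            ancestral_shared = bool(sis & grass)
            polymorphic = len(obs) > 1
            matches = bool(set(obs) & grass)
            if polymorphic:
                convergent = False
                partial = any(r in grass and r not in sis for r in obs)
            else:
                res = obs[0] if obs else None
                convergent = res is not None and res in grass and res not in sis
                partial = False
            if convergent:
                n_conv += 1
            if partial:
                n_partial += 1
                if mode == "any_member":
                    n_conv += 1
            site_rows.append(
                {
                    "clade": clade,
                    "position": entry.position,
                    "residues": ",".join(obs),
                    "matches_c4_grass": matches,
                    "differs_from_c3_sister": bool(set(obs) - sis),
                    "polymorphic": polymorphic,
                    "ancestral_shared": ancestral_shared,
                    "convergent": convergent,
                    "partial": partial,
                }
            )
        count_rows.append(
            {
                "clade": clade,
                "n_convergent": n_conv,
                "n_partial": n_partial,
                "n_catalog_sites": len(catalog),
                "fraction": n_conv / denom,
            }
        )
    return ConvergenceReport(pd.DataFrame(site_rows), pd.DataFrame(count_rows))
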