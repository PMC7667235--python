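"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its config plus seed, emitting the
same structures the readers produce: an isotope survey with C3/C4 modes, a
piecewise-linear-saturating A/Ci response, gene families containing
non-overlapping assembly fragments and overlapping paralogs, per-copy read
counts with known RPKM targets, and protein alignments with planted
convergent residues. Ground-truth labels travel with the data so downstream
recovery can be checked exactly.

Default parameters emulate a real herbarium/greenhouse study of the
Nyctaginaceae: C3 delta13C around -27.0 +/- 1.5 permil and C4 around
-12.5 +/- 1.2 (draws truncated to [-32, -9]); Ci/Ca near 0.33 for C4
leaves and 0.60 for C3 leaves; ~13 CO2 steps down to near the compensation
point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Alignment, Orthogroup, SequenceSet
from .phenotype import AciCurve
from .convergence import SiteCatalog

__all__ = [
    "GenusSpec",
    "SurveyConfig",
    "AciConfig",
    "FamilyConfig",
    "gen_isotope_survey",
    "gen_aci_curve",
    "gen_gene_families",
    "gen_expression_counts",
    "gen_convergence_alignment",
    "table1_survey_config",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
# one fixed codon per amino acid, for deterministic back-translation
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_AA1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}


# ---------------------------------------------------------------------------
# Isotope survey


@dataclass(frozen=True)
class GenusSpec:
    name: str
    n_species: int
    pathway: str  # "C3" | "C4"
    min_replicates: int = 2
    max_replicates: int = 4
    tribe: str = "Nyctagineae"


@dataclass
class SurveyConfig:
    genera: list[GenusSpec]
    c3_mean: float = -27.0
    c3_sd: float = 1.5
    c4_mean: float = -12.5
    c4_sd: float = 1.2
    lower: float = -32.0
    upper: float = -9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c3_sd <= 0 or self.c4_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if self.c4_mean <= self.c3_mean:
            raise ValueError("C4 mean must be less negative than C3 mean")


def table1_survey_config(seed: int = 0) -> SurveyConfig:
    """A survey design mirroring the published per-genus sampling effort:
    21 genera with isotope values, of which Allionia, Boerhavia and Okenia
    are fully C4 and the rest C3."""
    g = [
        GenusSpec("Salpianthus", 3, "C3", tribe="Boldoeae"),
        GenusSpec("Phaeoptilum", 1, "C3", tribe="Bougainvilleeae"),
        GenusSpec("Cryptocarpus", 1, "C3", tribe="Caribeeae"),
        GenusSpec("Colignonia", 6, "C3", tribe="Colignonieae"),
        GenusSpec("Andradea", 1, "C3", tribe="Leucastereae"),
        GenusSpec("Leucaster", 1, "C3", tribe="Leucastereae"),
        GenusSpec("Ramisia", 1, "C3", tribe="Leucastereae"),
        GenusSpec("Abronia", 20, "C3"),
        GenusSpec("Acleisanthes", 14, "C3"),
        GenusSpec("Allionia", 2, "C4"),
        GenusSpec("Anulocaulis", 5, "C3"),
        GenusSpec("Boerhavia", 43, "C4"),
        GenusSpec("Commicarpus", 23, "C3"),
        GenusSpec("Cyphomeris", 2, "C3"),
        GenusSpec("Mirabilis", 23, "C3"),
        GenusSpec("Nyctaginia", 1, "C3"),
        GenusSpec("Okenia", 4, "C4"),
        GenusSpec("Tripterocalyx", 4, "C3"),
        GenusSpec("Pisoniella", 1, "C3", tribe="Pisonieae"),
        GenusSpec("Grajalesia", 1, "C3", tribe="Pisonieae"),
        GenusSpec("Cephalotomandra", 1, "C3", tribe="Pisonieae"),
    ]
    return SurveyConfig(genera=g, seed=seed)


def gen_isotope_survey(config: SurveyConfig) -> pd.DataFrame:
    """Per-species replicate delta13C draws from the genus pathway mode.

    Draws are normal, truncated to [lower, upper]; the ground-truth pathway
    label is attached per record. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for genus in config.genera:
        mu, sd = (
            (config.c4_mean, config.c4_sd)
            if genus.pathway == "C4"
            else (config.c3_mean, config.c3_sd)
        )
        a = (config.lower - mu) / sd
        b = (config.upper - mu) / sd
        for si in range(genus.n_species):
            species = f"{genus.name.lower()}_sp{si + 1:03d}"
            n_rep = int(rng.integers(genus.min_replicates, genus.max_replicates + 1))
            draws = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n_rep, random_state=rng)
            for ri, v in enumerate(draws):
                rows.append(
                    {
                        "specimen_id": f"{species}_v{ri + 1}",
                        "tribe": genus.tribe,
                        "genus": genus.name,
                        "species": species,
                        "delta13c": float(v),
                        "true_pathway": genus.pathway,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# A/Ci curves


@dataclass
class AciConfig:
    """Non-rectangular-hyperbola A/Ci response.

    The noiseless assimilation rate is the smaller root of the hyperbola
    combining the CO2-limited line v = slope*(Ci - gamma) with the
    CO2-saturated ceiling a_max at curvature theta; below the compensation
    point (v <= 0) the response is exactly the line. Stomatal conductance
    is derived from A via the 1.6 water/CO2 diffusivity ratio with a small
    floor — generator plumbing, not a stomatal model.
    """

    slope: float = 0.25  # mol m-2 s-1
    gamma: float = 4.5  # umol mol-1
    a_max: float = 31.3  # umol m-2 s-1
    theta: float = 1.0  # 1.0 = piecewise linear-saturating (Blackman) response
    ci_ca_ratio: float = 0.33
    ca_steps: tuple[float, ...] = (
        1200, 400, 350, 300, 250, 200, 150, 120, 90, 70, 50, 30, 20,
    )
    noise_sd: float = 0.0  # umol m-2 s-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.a_max <= 0:
            raise ValueError("a_max must be positive")
        if not (0 < self.theta <= 1):
            raise ValueError("theta must be in (0, 1]")
        if not (0 < self.ci_ca_ratio < 1):
            raise ValueError(
                "ci_ca_ratio must be in (0, 1): Ci must stay below Ca"
            )


def _hyperbola(v: np.ndarray, a_max: float, theta: float) -> np.ndarray:
    s = v + a_max
    return (s - np.sqrt(s * s - 4.0 * theta * v * a_max)) / (2.0 * theta)


def gen_aci_curve(config: AciConfig) -> AciCurve:
    """Simulate one stepped A/Ci measurement sequence."""
    rng = np.random.default_rng(config.seed)
    ca = np.asarray(config.ca_steps, dtype=float)
    ci = config.ci_ca_ratio * ca
    v = config.slope * (ci - config.gamma)
    a_star = np.where(v <= 0, v, _hyperbola(np.maximum(v, 0.0), config.a_max, config.theta))
    noise = rng.normal(0.0, config.noise_sd, size=len(ca)) if config.noise_sd > 0 else 0.0
    a = a_star + noise
    gs = 1.6 * np.maximum(a, 0.01) / (ca - ci)
    return AciCurve(ca=ca, ci=ci, a=a, gs=gs)


# ---------------------------------------------------------------------------
# Gene families


@dataclass
class FamilyConfig:
    n_species: int = 53
    n_families: int = 50
    protein_length: tuple[int, int] = (80, 300)
    presence_prob: float = 0.9
    fragment_prob: float = 0.1
    paralog_prob: float = 0.1
    fragment_gap_columns: int = 5
    paralog_overlap_frac: float = 1.0
    mutation_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.presence_prob, self.fragment_prob, self.paralog_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.fragment_prob + self.paralog_prob > 1:
            raise ValueError("fragment_prob + paralog_prob must not exceed 1")
        if self.fragment_gap_columns < 1:
            raise ValueError("fragment_gap_columns must be >= 1")
        if self.paralog_overlap_frac <= 0.10:
            raise ValueError(
                "paralog_overlap_frac must exceed the 0.10 merge threshold "
                "so ground truth stays unambiguous"
            )


def _mutate(rng: np.random.Generator, protein: str, rate: float) -> str:
    chars = list(protein)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = _AA[rng.integers(len(_AA))]
    return "".join(chars)


def _backtranslate(protein: str) -> str:
    return "".join(_CODON[c] for c in protein)


def gen_gene_families(config: FamilyConfig
                      ) -> tuple[list[Orthogroup], dict[str, Alignment], SequenceSet, pd.DataFrame]:
    """Gene families with planted single-copy / fragment / paralog structure.

    Per family a master protein is sampled; each present species receives a
    mutated copy which, with ``fragment_prob``, is split into two aligned
    fragments separated by at least ``fragment_gap_columns`` all-gap columns
    (zero overlap), or, with ``paralog_prob``, is joined by a second
    full-length paralog (aligned overlap 1). Returns the orthogroup table,
    per-family protein alignments, the CDS set back-translating every row,
    and a truth table with columns og_id, species, label in
    {single, fragments, paralogs}.
    """
    rng = np.random.default_rng(config.seed)
    species = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    ogs: list[Orthogroup] = []
    alignments: dict[str, Alignment] = {}
    cds_ids: list[str] = []
    cds_seqs: list[str] = []
    truth_rows = []
    lo, hi = config.protein_length
    for fi in range(config.n_families):
        og_id = f"OG{fi + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        master = "".join(_AA[i] for i in rng.integers(len(_AA), size=length))
        members: dict[str, list[str]] = {sp: [] for sp in species}
        ids, rows = [], []
        for sp in species:
            if rng.random() >= config.presence_prob:
                continue
            copy = _mutate(rng, master, config.mutation_rate)
            u = rng.random()
            if u < config.fragment_prob and length >= 2 * config.fragment_gap_columns + 10:
                g = config.fragment_gap_columns
                split = int(rng.integers(5, length - g - 5))
                frag_a = copy[:split] + "-" * (length - split)
                frag_b = "-" * (split + g) + copy[split + g :]
                for k, frag in ((1, frag_a), (2, frag_b)):
                    sid = f"{sp}_{og_id}_f{k}"
                    members[sp].append(sid)
                    ids.append(sid)
                    rows.append(frag)
                    cds_ids.append(sid)
                    cds_seqs.append(_backtranslate(frag.replace("-", "")))
                label = "fragments"
            elif u < config.fragment_prob + config.paralog_prob:
                paralog = _mutate(rng, master, 4 * config.mutation_rate)
                for k, seq in ((1, copy), (2, paralog)):
                    sid = f"{sp}_{og_id}_p{k}"
                    members[sp].append(sid)
                    ids.append(sid)
                    rows.append(seq)
                    cds_ids.append(sid)
                    cds_seqs.append(_backtranslate(seq))
                label = "paralogs"
            else:
                sid = f"{sp}_{og_id}"
                members[sp].append(sid)
                ids.append(sid)
                rows.append(copy)
                cds_ids.append(sid)
                cds_seqs.append(_backtranslate(copy))
                label = "single"
            truth_rows.append({"og_id": og_id, "species": sp, "label": label})
        aln = Alignment(ids=ids, seqs=rows, alphabet="protein")
        ogs.append(Orthogroup(og_id=og_id, members=members, alignment=aln))
        alignments[og_id] = aln
    cds = SequenceSet(ids=cds_ids, seqs=cds_seqs, alphabet="nucleotide")
    return ogs, alignments, cds, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Expression counts


def gen_expression_counts(copies: list[tuple[str, int, float]], total_reads: float,
                          seed: int = 0) -> pd.DataFrame:
    """Poisson read counts around RPKM targets.

    ``copies`` holds (name, transcript length in bp, target RPKM); the
    expected count is target * (length/1000) * (total_reads/1e6).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, length_bp, target in copies:
        if length_bp <= 0:
            raise ValueError(f"{name}: transcript length must be positive")
        if target < 0:
            raise ValueError(f"{name}: RPKM target must be non-negative")
        expected = target * (length_bp / 1000.0) * (total_reads / 1e6)
        count = int(rng.poisson(expected)) if expected > 0 else 0
        rows.append(
            {
                "copy": name,
                "transcript_len_bp": length_bp,
                "read_count": count,
                "total_reads": total_reads,
                "target_rpkm": target,
                "expected_count": expected,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Convergence alignments


def gen_convergence_alignment(catalog: SiteCatalog,
                              design: dict[str, dict[int, str]],
                              members_per_clade: int = 3,
                              reference_id: str = "reference",
                              reference_length: int | None = None,
                              leading_gap_columns: int = 0,
                              background_noise: float = 0.01,
                              seed: int = 0) -> tuple[Alignment, str]:
    """Protein alignment with planted residues at catalog sites.

    The reference row carries the catalog's C3 residues at catalog positions
    (known residue numbering; optionally offset by planted leading gap
    columns to exercise coordinate mapping). Each designed clade's members
    carry the designed residue (3-letter code) at each catalog column, plus
    background substitutions at non-catalog columns. Designing a site absent
    from the catalog is an error.
    """
    rng = np.random.default_rng(seed)
    positions = catalog.positions
    for clade, sites in design.items():
        extra = set(sites) - set(positions)
        if extra:
            raise ValueError(f"clade {clade!r} designs sites not in catalog: {sorted(extra)}")
    ref_len = reference_length if reference_length is not None else max(positions) + 10
    if ref_len < max(positions):
        raise ValueError("reference_length shorter than the last catalog position")
    ref = [_AA[i] for i in rng.integers(len(_AA), size=ref_len)]
    for entry in catalog:
        ref[entry.position - 1] = _AA1[entry.c3_reference_residue]
    ref_seq = "".join(ref)
    pad = leading_gap_columns
    ids = [reference_id]
    rows = ["-" * pad + ref_seq]
    catalog_cols = {pad + p - 1 for p in positions}
    for clade, sites in design.items():
        for mi in range(members_per_clade):
            chars = list(ref_seq)
            for pos, res in sites.items():
                chars[pos - 1] = _AA1[res]
            for j in range(len(chars)):
                if (pad + j) not in catalog_cols and rng.random() < background_noise:
                    chars[j] = _AA[rng.integers(len(_AA))]
            # members carry residues over the reference's planted gap columns
            lead = "".join(_AA[i] for i in rng.integers(len(_AA), size=pad))
            ids.append(f"{clade}_m{mi + 1}")
            rows.append(lead + "".join(chars))
    aln = Alignment(ids=ids, seqs=rows, alphabet="protein")
    return aln, reference_id
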