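"""Leaf gas-exchange, enzyme-assay and ultrastructure arithmetic.

The A/Ci response (net CO2 assimilation rate *A* against intercellular CO2
*Ci*) yields the classic C4 diagnostics: the initial slope below Ci = 100
umol/mol is the carboxylation efficiency, its x-intercept is the CO2
compensation point Gamma, and the ratio A400/A1200 measures how saturated
photosynthesis already is at ambient CO2. Enzyme activities are derived from
NAD(P)(H) absorbance kinetics at 340 nm, chlorophyll from the two-wavelength
80%-acetone equations, and the biochemical subtype call compares the two
decarboxylase activities against the photosynthetic rate they must sustain.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AciCurve",
    "AciMetrics",
    "EnzymePanel",
    "GammaEstimate",
    "SubtypeCall",
    "ChlorophyllResult",
    "fit_initial_slope",
    "estimate_gamma",
    "point_metrics",
    "chlorophyll_from_absorbance",
    "activity_from_a340",
    "call_subtype",
    "ultrastructure_summary",
    "one_tailed_compare",
]

# molar masses, g/mol
_CHL_A_MASS = 893.5
_CHL_B_MASS = 907.5


@dataclass
class AciCurve:
    """Stepped CO2-response measurements for one leaf.

    Arrays are ordered as measured; units: ca/ci umol/mol, a umol m-2 s-1,
    gs mol m-2 s-1. Ci must be below Ca at every step.
    """

    ca: np.ndarray
    ci: np.ndarray
    a: np.ndarray
    gs: np.ndarray
    leaf_t: float | None = None
    pfd: float | None = None

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.ci = np.asarray(self.ci, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.gs = np.asarray(self.gs, dtype=float)
        n = len(self.ca)
        if not (len(self.ci) == len(self.a) == len(self.gs) == n):
            raise ValueError("ca, ci, a, gs must have equal length")
        if np.any(self.ci >= self.ca):
            bad = int(np.argmax(self.ci >= self.ca))
            raise ValueError(f"ci >= ca at step {bad} (ci={self.ci[bad]}, ca={self.ca[bad]})")

    def __len__(self) -> int:
        return len(self.ca)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "AciCurve":
        return cls(ca=df["ca"].to_numpy(), ci=df["ci"].to_numpy(),
                   a=df["a"].to_numpy(), gs=df["gs"].to_numpy(), **kw)


@dataclass(frozen=True)
class GammaEstimate:
    gamma: float
    clamped: bool = False  # True when the fitted x-intercept was negative


@dataclass(frozen=True)
class AciMetrics:
    a400: float
    a1200: float
    a_ratio: float
    initial_slope: float
    norm_ce: float  # initial_slope / a1200
    gamma: float
    wue: float  # a400 / gs400
    ci_ca: float  # at the 400 step


@dataclass(frozen=True)
class EnzymePanel:
    """Enzyme activities per leaf area (umol m-2 s-1) plus pigments.

    ``chlorophyll`` is total chlorophyll in mmol m-2; per-chlorophyll
    activities (mmol per mol Chl per s) are derived on access.
    """

    pepc: float
    nadp_me: float
    nad_me: float
    chlorophyll: float | None = None
    chl_ab_ratio: float | None = None

    def per_chlorophyll(self, activity_area: float) -> float:
        if self.chlorophyll is None or self.chlorophyll <= 0:
            raise ValueError("chlorophyll content required for per-chlorophyll activity")
        return activity_area / self.chlorophyll


@dataclass(frozen=True)
class SubtypeCall:
    subtype: str  # "NADP-ME" | "NAD-ME" | "none"
    robust: bool
    warning: bool


@dataclass(frozen=True)
class ChlorophyllResult:
    chl_a_mg_l: float
    chl_b_mg_l: float
    chl_a_mmol_m2: float
    chl_b_mmol_m2: float
    total_mmol_m2: float
    ab_ratio: float  # molar


def fit_initial_slope(curve: AciCurve, ci_cutoff: float = 100.0) -> tuple[float, float]:
    """Ordinary least squares of A on Ci over steps with Ci below the cutoff.

    The slope of A (umol m-2 s-1) on Ci (umol/mol) is the carboxylation
    efficiency in mol m-2 s-1. Needs at least two qualifying steps.
    """
    mask = curve.ci < ci_cutoff
    if mask.sum() < 2:
        raise ValueError(
            f"need >= 2 steps with ci < {ci_cutoff}, have {int(mask.sum())}"
        )
    slope, intercept = np.polyfit(curve.ci[mask], curve.a[mask], 1)
    return float(slope), float(intercept)


def estimate_gamma(curve: AciCurve, ci_cutoff: float = 100.0,
                   method: str = "x_intercept") -> GammaEstimate:
    """CO2 compensation point Gamma (umol/mol).

    ``x_intercept`` (default): -intercept/slope of the low-Ci regression,
    floored at zero. ``interpolation``: linear interpolation between the
    measured steps bracketing A = 0.
    """
    if method == "x_intercept":
        slope, intercept = fit_initial_slope(curve, ci_cutoff)
        if slope <= 0:
            raise ValueError(f"non-positive initial slope ({slope}); cannot estimate gamma")
        gamma = -intercept / slope
        if gamma < 0:
            return GammaEstimate(0.0, clamped=True)
        return GammaEstimate(float(gamma))
    if method == "interpolation":
        order = np.argsort(curve.ci)
        ci, a = curve.ci[order], curve.a[order]
        sign = np.sign(a)
        crossings = np.nonzero(np.diff(sign >= 0))[0]
        if len(crossings) == 0:
            if np.all(a > 0):
                return GammaEstimate(0.0, clamped=True)
            raise ValueError("A never crosses zero on this curve")
        i = crossings[0]
        g = ci[i] - a[i] * (ci[i + 1] - ci[i]) / (a[i + 1] - a[i])
        return GammaEstimate(float(max(g, 0.0)), clamped=g < 0)
    raise ValueError(f"unknown gamma method {method!r}")


def _step_at(curve: AciCurve, ca_target: float, tol: float) -> int:
    d = np.abs(curve.ca - ca_target)
    i = int(np.argmin(d))
    if d[i] > tol:
        raise ValueError(f"no step within +/-{tol} of ca={ca_target} (closest {curve.ca[i]})")
    return i


def point_metrics(curve: AciCurve, ci_cutoff: float = 100.0, ca_tol: float = 25.0) -> AciMetrics:
    """Derived statistics at the 400 and 1200 umol/mol ambient-CO2 steps.

    A400/A1200 measures CO2 saturation at ambient; intrinsic water-use
    efficiency is A/gs at the 400 step; the normalized carboxylation
    efficiency divides the initial slope by A1200 to correct for differences
    in photosynthetic capacity.
    """
    i400 = _step_at(curve, 400.0, ca_tol)
    i1200 = _step_at(curve, 1200.0, ca_tol)
    a400 = float(curve.a[i400])
    a1200 = float(curve.a[i1200])
    slope, _ = fit_initial_slope(curve, ci_cutoff)
    gamma = estimate_gamma(curve, ci_cutoff).gamma
    return AciMetrics(
        a400=a400,
        a1200=a1200,
        a_ratio=a400 / a1200,
        initial_slope=slope,
        norm_ce=slope / a1200,
        gamma=gamma,
        wue=a400 / float(curve.gs[i400]),
        ci_ca=float(curve.ci[i400] / curve.ca[i400]),
    )


def chlorophyll_from_absorbance(a645: float, a663: float,
                                dilution_l_per_m2: float = 1.0) -> ChlorophyllResult:
    """Chlorophyll a/b from 80%-acetone absorbances at 645 and 663 nm.

    mg/L via chl_a = 12.7*A663 - 2.69*A645 and chl_b = 22.9*A645 - 4.68*A663,
    converted to mmol per m2 leaf using molar masses 893.5 (a) and 907.5 (b)
    and the extract volume per leaf area (L/m2). The a/b ratio is molar.
    """
    if a645 < 0 or a663 < 0:
        raise ValueError("absorbances must be non-negative")
    chl_a = 12.7 * a663 - 2.69 * a645
    chl_b = 22.9 * a645 - 4.68 * a663
    if chl_a < 0 or chl_b < 0:
        raise ValueError(
            "negative chlorophyll concentration computed; 645/663 absorbances may be swapped"
        )
    a_mmol = chl_a / _CHL_A_MASS * dilution_l_per_m2
    b_mmol = chl_b / _CHL_B_MASS * dilution_l_per_m2
    ratio = a_mmol / b_mmol if b_mmol > 0 else float("inf") if a_mmol > 0 else 0.0
    return ChlorophyllResult(chl_a, chl_b, a_mmol, b_mmol, a_mmol + b_mmol, ratio)


def activity_from_a340(slope_a340_per_min: float, extract_vol_ml: float = 1.0,
                       assay_vol_ml: float = 1.0, aliquot_ml: float = 1.0,
                       leaf_area_cm2: float = 1.0, epsilon: float = 6.22,
                       path_cm: float = 1.0) -> float:
    """Enzyme activity per leaf area from an NAD(P)(H) A340 time course.

    |slope|/(epsilon*path) gives mM/min in the cuvette; scaled by assay
    volume to umol/min, by extract/aliquot to the whole extract, divided by
    leaf area (m2) and by 60 to umol m-2 s-1. epsilon defaults to 6.22
    mM-1 cm-1 for NAD(P)H at 340 nm.
    """
    if leaf_area_cm2 <= 0:
        raise ValueError("leaf area must be positive")
    if extract_vol_ml <= 0 or assay_vol_ml <= 0 or aliquot_ml <= 0:
        raise ValueError("volumes must be positive")
    rate_mm_per_min = abs(slope_a340_per_min) / (epsilon * path_cm)
    umol_per_min_cuvette = rate_mm_per_min * assay_vol_ml  # mM * mL = umol
    umol_per_min_extract = umol_per_min_cuvette * extract_vol_ml / aliquot_ml
    area_m2 = leaf_area_cm2 * 1e-4
    return umol_per_min_extract / area_m2 / 60.0


def call_subtype(panel: EnzymePanel, a400: float,
                 none_floor: float = 0.2, robust_factor: float = 1.0,
                 warn_factor: float = 0.5) -> SubtypeCall:
    """Biochemical-subtype decision from decarboxylase activities.

    The dominant decarboxylase (NADP-ME vs NAD-ME, per leaf area) is the
    subtype call, provided it can plausibly sustain the measured A400:
    robust when its activity >= A400, otherwise flagged with a warning.
    When both decarboxylases fall below ``none_floor``*A400 the leaf is
    C3-consistent and the call is "none". PCK is never assayed by this
    panel, so no PCK branch exists.
    """
    best_name, best = max(
        (("NADP-ME", panel.nadp_me), ("NAD-ME", panel.nad_me)), key=lambda kv: kv[1]
    )
    if panel.nadp_me < none_floor * a400 and panel.nad_me < none_floor * a400:
        return SubtypeCall("none", robust=False, warning=False)
    robust = best >= robust_factor * a400
    warning = not robust
    if not robust and best < warn_factor * a400:
        warning = True  # weak support; still reported with the warning flag
    return SubtypeCall(best_name, robust=robust, warning=warning)


def one_tailed_compare(group_a, group_b) -> float:
    """Welch two-sample t test, one-tailed in the direction of the observed
    difference (so swapping the groups leaves p unchanged).

    Identical groups, or two zero-variance groups with equal means, give the
    symmetric-null value p = 0.5.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return 0.5 if np.mean(a) == np.mean(b) else 0.0
    if np.mean(a) == np.mean(b):
        return 0.5
    t, p_two = stats.ttest_ind(a, b, equal_var=False)
    return float(p_two) / 2.0


# ---------------------------------------------------------------------------
# Ultrastructure


def _compact_letters(groups: list[str], significant) -> dict[str, str]:
    """Compact letter display: groups not significantly different share a
    letter. ``significant(g, h)`` -> True when g and h differ."""
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(not significant(g, h) for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # drop sets fully contained in another
    keep = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    out: dict[str, str] = {g: "" for g in groups}
    for letter, s in zip(string.ascii_lowercase, keep):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def ultrastructure_summary(cells: pd.DataFrame, organelles: pd.DataFrame,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Bundle-sheath ultrastructure metrics per species with group letters.

    ``cells``: columns species, plant, cell, cell_area (um2).
    ``organelles``: columns species, plant, cell, kind in
    {chloroplast, mitochondrion}, area (um2); one row per organelle.

    Per species: mean cell area; percent of cell area covered by each
    organelle kind (averaged per plant, then across plants); median count
    per cell with range; mean organelle area. Letters come from one-way
    ANOVA plus Tukey HSD at ``alpha`` on per-plant means; species measured
    in a single plant get no letters.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    merged_cols = ["species", "plant", "cell"]
    per_cell = cells.copy()
    for kind in ("chloroplast", "mitochondrion"):
        sub = organelles[organelles["kind"] == kind]
        agg = sub.groupby(merged_cols)["area"].agg(total="sum", n="count").reset_index()
        per_cell = per_cell.merge(agg, on=merged_cols, how="left").rename(
            columns={"total": f"{kind}_area", "n": f"{kind}_n"}
        )
    per_cell = per_cell.fillna({"chloroplast_area": 0.0, "chloroplast_n": 0,
                                "mitochondrion_area": 0.0, "mitochondrion_n": 0})
    per_cell["chloroplast_cov"] = per_cell["chloroplast_area"] / per_cell["cell_area"] * 100
    per_cell["mitochondrion_cov"] = per_cell["mitochondrion_area"] / per_cell["cell_area"] * 100

    metric_cols = ["cell_area", "chloroplast_cov", "mitochondrion_cov"]
    per_plant = per_cell.groupby(["species", "plant"])[metric_cols].mean().reset_index()

    # Tukey letters on per-plant means, one metric at a time
    letters: dict[str, dict[str, str]] = {}
    species_list = list(per_plant["species"].unique())
    multi_plant = [
        sp for sp in species_list
        if (per_plant["species"] == sp).sum() >= 2
    ]
    for metric in metric_cols:
        if len(multi_plant) < 2:
            letters[metric] = {}
            continue
        sub = per_plant[per_plant["species"].isin(multi_plant)]
        if sub[metric].var() == 0:
            letters[metric] = {sp: "a" for sp in multi_plant}
            continue
        tk = pairwise_tukeyhsd(sub[metric], sub["species"], alpha=alpha)
        pairs = {}
        res = tk.summary().data[1:]
        for row in res:
            g1, g2, *_rest, reject = row
            pairs[frozenset((str(g1), str(g2)))] = bool(reject)

        def sig(g, h, _pairs=pairs):
            return _pairs.get(frozenset((g, h)), False)

        order = (
            sub.groupby("species")[metric].mean().sort_values().index.tolist()
        )
        letters[metric] = _compact_letters(order, sig)

    rows = []
    for sp in species_list:
        sp_cells = per_cell[per_cell["species"] == sp]
        sp_plants = per_plant[per_plant["species"] == sp]
        sp_org = organelles[organelles["species"] == sp]
        row = {
            "species": sp,
            "n_plants": len(sp_plants),
            "cell_area_mean": sp_plants["cell_area"].mean(),
            "chloroplast_cov_pct": sp_plants["chloroplast_cov"].mean(),
            "mitochondrion_cov_pct": sp_plants["mitochondrion_cov"].mean(),
        }
        for kind in ("chloroplast", "mitochondrion"):
            counts = sp_cells[f"{kind}_n"]
            row[f"{kind}_per_cell_median"] = counts.median()
            row[f"{kind}_per_cell_min"] = counts.min()
            row[f"{kind}_per_cell_max"] = counts.max()
            areas = sp_org[sp_org["kind"] == kind]["area"]
            row[f"{kind}_area_mean"] = areas.mean() if len(areas) else float("nan")
        out_name = {"cell_area": "cell_area_mean",
                    "chloroplast_cov": "chloroplast_cov_pct",
                    "mitochondrion_cov": "mitochondrion_cov_pct"}
        for metric in metric_cols:
            row[f"{out_name[metric]}_letter"] = letters.get(metric, {}).get(sp, "")
        rows.append(row)
    return pd.DataFrame(rows)
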