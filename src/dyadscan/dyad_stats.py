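"""Dyad contingency tables, effect ratios, the relative ratio test and
group descriptives.

A *dyad* is a parent-category x offspring-sex pairing (e.g. mother->son).
For each dyad the cohort is cross-tabulated as exposure (positive dementia
history in the specified parent) against case status, giving a 2x2 table.
The per-dyad effect is either a risk ratio (ratio of exposure proportions,
the default, matching the published tables) or an odds ratio.

Two dyads are contrasted through the relative ratio ``phi = effect_1 /
effect_2`` with the normal deviate

    z = ln(phi) / sqrt(v_1 + v_2)

where ``v_i`` is a per-dyad log-scale variance.  Two variance rules are
provided: ``paper_literal`` uses ``1/(n p (1-p)) + 1/(n' p' (1-p'))`` for
each dyad (algebraically the Woolf log-odds-ratio variance of that dyad —
``n p = a`` and ``n (1-p) = b`` make the first term ``1/a + 1/b``);
``pooled_woolf`` uses the variance that matches the chosen effect measure
(Woolf for odds ratios, the standard log-risk-ratio variance for risk
ratios).  Two-sided p-values come from the standard normal; no multiplicity
correction is applied by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import CohortTable, exposure_vector, same_town_vector, normalize_apoe
from .errors import DegenerateEstimateError, DegenerateTableError

Measure = Literal["risk_ratio", "odds_ratio"]
VarianceRule = Literal["paper_literal", "pooled_woolf"]

_Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# specs and tables


@dataclass(frozen=True)
class DyadSpec:
    """A parent category crossed with an offspring sex."""

    parent: str  # father | mother | any
    offspring_sex: str  # male | female | any

    def __post_init__(self) -> None:
        if self.parent not in ("father", "mother", "any"):
            raise ValueError(f"bad parent {self.parent!r}")
        if self.offspring_sex not in ("male", "female", "any"):
            raise ValueError(f"bad offspring_sex {self.offspring_sex!r}")

    @property
    def label(self) -> str:
        child = {"male": "son", "female": "daughter", "any": "any child"}[
            self.offspring_sex
        ]
        parent = {"father": "father", "mother": "mother", "any": "any parent"}[
            self.parent
        ]
        return f"{parent} -> {child}"


#: the seven dyads of the published comparison matrix, in row order.
TABLE2_SPECS: tuple[DyadSpec, ...] = (
    DyadSpec("father", "male"),
    DyadSpec("father", "female"),
    DyadSpec("any", "female"),
    DyadSpec("mother", "female"),
    DyadSpec("mother", "male"),
    DyadSpec("any", "male"),
    DyadSpec("any", "any"),
)


@dataclass
class DyadTable:
    """Exposure x status counts for one dyad.

    ``a``/``c`` are exposed cases/controls, ``n_case``/``n_ctrl`` the
    eligible totals; ``b``/``d`` and the exposure proportions are derived.
    """

    spec: DyadSpec
    a: int
    n_case: int
    c: int
    n_ctrl: int

    def __post_init__(self) -> None:
        if not (0 <= self.a <= self.n_case):
            raise ValueError("need 0 <= a <= n_case")
        if not (0 <= self.c <= self.n_ctrl):
            raise ValueError("need 0 <= c <= n_ctrl")

    @property
    def b(self) -> int:
        return self.n_case - self.a

    @property
    def d(self) -> int:
        return self.n_ctrl - self.c

    @property
    def p(self) -> float:
        return self.a / self.n_case

    @property
    def p_prime(self) -> float:
        return self.c / self.n_ctrl

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_ctrl


def build_dyad_table(cohort: CohortTable, spec: DyadSpec) -> DyadTable:
    """Cross-tabulate one dyad from a cohort.

    Subjects excluded by the dyad eligibility rule (unknown history, both
    parents affected) are dropped from both margins.
    """
    frame = cohort.frame
    if spec.offspring_sex == "any":
        sex_mask = np.ones(len(frame), dtype=bool)
    else:
        sex_mask = (frame["sex"] == spec.offspring_sex).to_numpy()
    exposed, eligible = exposure_vector(frame, spec.parent)
    case = (frame["status"] == "case").to_numpy()
    in_scope = sex_mask & eligible
    a = int((in_scope & case & exposed).sum())
    n_case = int((in_scope & case).sum())
    c = int((in_scope & ~case & exposed).sum())
    n_ctrl = int((in_scope & ~case).sum())
    if n_case == 0 or n_ctrl == 0:
        raise DegenerateTableError(
            f"dyad {spec.label!r}: empty margin (n_case={n_case}, n_ctrl={n_ctrl})"
        )
    return DyadTable(spec, a, n_case, c, n_ctrl)


# ---------------------------------------------------------------------------
# effect estimates


@dataclass
class EffectEstimate:
    measure: str
    value: float
    log_se: float
    ci95: tuple[float, float]
    one_sided: bool = False

    @property
    def log_var(self) -> float:
        return self.log_se**2


def _wald_ci(value: float, log_se: float) -> tuple[float, float]:
    lo = math.exp(math.log(value) - _Z95 * log_se)
    hi = math.exp(math.log(value) + _Z95 * log_se)
    return (lo, hi)


def risk_ratio(table: DyadTable, continuity: bool = False) -> EffectEstimate:
    """Ratio of case to control exposure proportions with a Wald CI.

    ``continuity=True`` adds 0.5 to all four cells (Haldane–Anscombe) before
    computing; it is never applied silently.  A zero control-exposure cell
    without continuity raises; a zero case-exposure cell yields value 0 with
    a one-sided CI flag.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n_case, n_ctrl = a + b, c + d
    if c == 0:
        raise DegenerateEstimateError(
            f"dyad {table.spec.label!r}: zero exposed controls gives an infinite "
            "risk ratio; re-run with continuity=True for Haldane–Anscombe cells"
        )
    p, pp = a / n_case, c / n_ctrl
    if a == 0:
        # one-sided: upper bound from the rule-of-three style 0.5 cell
        upper = ((0.5 / (n_case + 0.5)) / pp) * math.exp(
            _Z95 * math.sqrt(1 / 0.5 + 1 / c)
        )
        return EffectEstimate("risk_ratio", 0.0, math.inf, (0.0, upper), one_sided=True)
    value = p / pp
    log_se = math.sqrt((1 - p) / a + (1 - pp) / c)
    return EffectEstimate("risk_ratio", value, log_se, _wald_ci(value, log_se))


def odds_ratio(table: DyadTable, continuity: bool = False) -> EffectEstimate:
    """Cross-product odds ratio with Woolf log-variance and Wald CI."""
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if continuity:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) == 0:
        raise DegenerateEstimateError(
            f"dyad {table.spec.label!r}: zero cell in the 2x2 table; re-run with "
            "continuity=True to apply the Haldane–Anscombe +0.5 correction"
        )
    value = (a * d) / (b * c)
    log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate("odds_ratio", value, log_se, _wald_ci(value, log_se))


def effect_estimate(
    table: DyadTable, measure: Measure = "risk_ratio", continuity: bool = False
) -> EffectEstimate:
    if measure == "risk_ratio":
        return risk_ratio(table, continuity=continuity)
    if measure == "odds_ratio":
        return odds_ratio(table, continuity=continuity)
    raise ValueError(f"unknown measure {measure!r}")


# ---------------------------------------------------------------------------
# dyad comparison


@dataclass
class DyadComparison:
    dyad_a: DyadSpec
    dyad_b: DyadSpec
    phi: float
    z: float
    p_two_sided: float
    mode: str
    variance_rule: str


def _literal_variance(table: DyadTable) -> float:
    p, pp = table.p, table.p_prime
    if p in (0.0, 1.0) or pp in (0.0, 1.0):
        raise DegenerateEstimateError(
            f"dyad {table.spec.label!r}: exposure proportion on the boundary, "
            "literal variance undefined"
        )
    return 1.0 / (table.n_case * p * (1 - p)) + 1.0 / (table.n_ctrl * pp * (1 - pp))


def compare_dyads(
    t1: DyadTable,
    t2: DyadTable,
    mode: Measure = "risk_ratio",
    variance_rule: VarianceRule = "pooled_woolf",
    continuity: bool = False,
) -> DyadComparison:
    """Relative ratio ``phi = effect(t1)/effect(t2)`` with z and two-sided p."""
    e1 = effect_estimate(t1, mode, continuity=continuity)
    e2 = effect_estimate(t2, mode, continuity=continuity)
    if e1.value <= 0 or e2.value <= 0 or not (
        math.isfinite(e1.value) and math.isfinite(e2.value)
    ):
        raise DegenerateEstimateError(
            f"non-finite or zero effect in {t1.spec.label!r} vs {t2.spec.label!r}"
        )
    phi = e1.value / e2.value
    if variance_rule == "paper_literal":
        v1, v2 = _literal_variance(t1), _literal_variance(t2)
    elif variance_rule == "pooled_woolf":
        v1, v2 = e1.log_var, e2.log_var
    else:
        raise ValueError(f"unknown variance_rule {variance_rule!r}")
    z = math.log(phi) / math.sqrt(v1 + v2)
    p = 2.0 * stats.norm.sf(abs(z))
    return DyadComparison(t1.spec, t2.spec, phi, z, float(p), mode, variance_rule)


# ---------------------------------------------------------------------------
# dyad matrix


@dataclass
class DyadMatrix:
    """Per-dyad effects plus the lower-triangular pairwise comparisons."""

    specs: tuple[DyadSpec, ...]
    tables: list[DyadTable | None]
    effects: list[EffectEstimate | None]
    cells: dict[tuple[int, int], DyadComparison]
    flagged: dict[tuple[int, int], str] = field(default_factory=dict)
    mode: str = "risk_ratio"
    variance_rule: str = "pooled_woolf"

    def comparison(self, i: int, j: int) -> DyadComparison:
        return self.cells[(i, j)]

    def to_frame(self) -> pd.DataFrame:
        """Rounded report mirroring the published matrix layout."""
        rows = []
        labels = [s.label for s in self.specs]
        for i, spec in enumerate(self.specs):
            t, e = self.tables[i], self.effects[i]
            row: dict[str, object] = {"dyad": spec.label}
            if t is not None:
                row["controls"] = f"{t.c}/{t.n_ctrl} ({t.p_prime:.3f})"
                row["cases"] = f"{t.a}/{t.n_case} ({t.p:.3f})"
            else:
                row["controls"] = row["cases"] = "degenerate"
            row["effect"] = f"{e.value:.2f}" if e is not None else "NA"
            for j in range(i):
                key = f"vs {labels[j]}"
                if (i, j) in self.cells:
                    c = self.cells[(i, j)]
                    row[key] = f"phi={c.phi:.3f}, p={c.p_two_sided:.3f}"
                else:
                    row[key] = self.flagged.get((i, j), "")
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """Full-precision JSON-ready representation."""
        out: dict = {
            "mode": self.mode,
            "variance_rule": self.variance_rule,
            "dyads": [],
            "comparisons": [],
        }
        for spec, t, e in zip(self.specs, self.tables, self.effects):
            entry: dict = {"dyad": spec.label}
            if t is not None:
                entry.update(
                    a=t.a, n_case=t.n_case, c=t.c, n_ctrl=t.n_ctrl, p=t.p,
                    p_prime=t.p_prime,
                )
            if e is not None:
                entry.update(
                    effect=e.value, log_se=e.log_se, ci95=list(e.ci95),
                    measure=e.measure,
                )
            out["dyads"].append(entry)
        for (i, j), c in sorted(self.cells.items()):
            out["comparisons"].append(
                {
                    "dyad_a": c.dyad_a.label,
                    "dyad_b": c.dyad_b.label,
                    "phi": c.phi,
                    "z": c.z,
                    "p_two_sided": c.p_two_sided,
                }
            )
        for (i, j), msg in sorted(self.flagged.items()):
            out["comparisons"].append(
                {
                    "dyad_a": self.specs[i].label,
                    "dyad_b": self.specs[j].label,
                    "error": msg,
                }
            )
        return out


def dyad_matrix(
    cohort: CohortTable,
    specs: Sequence[DyadSpec] = TABLE2_SPECS,
    mode: Measure = "risk_ratio",
    variance_rule: VarianceRule = "pooled_woolf",
) -> DyadMatrix:
    """All pairwise dyad comparisons in row/column order.

    Cell ``(i, j)`` (for ``i > j``) contrasts row dyad ``i`` against column
    dyad ``j`` (``phi = effect_i / effect_j``).  Degenerate dyads flag their
    cells but the matrix is still returned.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 dyad specs")
    specs = tuple(specs)
    tables: list[DyadTable | None] = []
    effects: list[EffectEstimate | None] = []
    errors: list[str | None] = []
    for spec in specs:
        try:
            t = build_dyad_table(cohort, spec)
            e = effect_estimate(t, mode)
            tables.append(t)
            effects.append(e)
            errors.append(None)
        except (DegenerateTableError, DegenerateEstimateError) as exc:
            tables.append(None)
            effects.append(None)
            errors.append(str(exc))
    cells: dict[tuple[int, int], DyadComparison] = {}
    flagged: dict[tuple[int, int], str] = {}
    for i in range(len(specs)):
        for j in range(i):
            if tables[i] is None or tables[j] is None:
                flagged[(i, j)] = errors[i] or errors[j] or "degenerate"
                continue
            try:
                cells[(i, j)] = compare_dyads(
                    tables[i], tables[j], mode=mode, variance_rule=variance_rule
                )
            except DegenerateEstimateError as exc:
                flagged[(i, j)] = str(exc)
    return DyadMatrix(specs, tables, effects, cells, flagged, mode, variance_rule)


# ---------------------------------------------------------------------------
# descriptive group comparisons


@dataclass
class GroupComparison:
    variable: str
    test: str  # chi_square | mann_whitney | none
    statistic: float | None
    p: float | None
    groups: dict[str, dict]
    note: str = ""


def _derived_columns(cohort: CohortTable) -> pd.DataFrame:
    frame = cohort.frame.copy()
    frame["same_town"] = same_town_vector(cohort.frame)
    onset = frame["age_of_onset"]
    frame["onset_class"] = np.where(
        onset.isna(), None, np.where(onset <= 65.0, "EOAD", "LOAD")
    )
    apoe = frame["apoe"]
    frame["apoe_e4_carrier"] = apoe.map(
        lambda v: None if v is None or pd.isna(v) else ("yes" if "e4" in v else "no")
    )
    sib = frame["siblings_with_dementia"]
    frame["sibling_history"] = np.where(
        sib.isna(), None, np.where(sib > 0, "yes", "no")
    )
    pat, mat = frame["paternal_history"], frame["maternal_history"]
    parent_any = np.where(
        (pat == "unknown") & (mat == "unknown"),
        None,
        np.where((pat == "yes") | (mat == "yes"), "yes", "no"),
    )
    # family history = any affected parent or sibling
    fam = np.where(
        (pat == "yes") | (mat == "yes") | (sib.fillna(0) > 0), "yes", "no"
    )
    fam = np.where(
        (pat == "unknown") & (mat == "unknown") & sib.isna(), None, fam
    )
    frame["parental_history"] = parent_any
    frame["family_history"] = fam
    return frame


#: variable name -> (kind, column)
_VARIABLE_KINDS: dict[str, str] = {
    "sex": "categorical",
    "education": "continuous",
    "age_at_assessment": "continuous",
    "age_of_onset": "continuous",
    "year_of_birth": "continuous",
    "apoe": "categorical",
    "apoe_e4_carrier": "categorical",
    "paternal_history": "categorical",
    "maternal_history": "categorical",
    "parental_history": "categorical",
    "family_history": "categorical",
    "sibling_history": "categorical",
    "same_town": "categorical",
    "onset_class": "categorical",
    "csf_abeta42": "continuous",
    "csf_ttau": "continuous",
    "csf_ptau": "continuous",
    "n_siblings": "continuous",
}

_GROUPINGS = {
    "case_vs_control": ("status", ("control", "case")),
    "eoad_vs_load": ("onset_class", ("EOAD", "LOAD")),
    "same_vs_different_town": ("same_town", ("same", "different")),
}

_DEFAULT_VARIABLES = {
    "case_vs_control": [
        "sex", "education", "age_of_onset", "apoe", "family_history",
        "paternal_history", "maternal_history", "sibling_history", "same_town",
    ],
    "eoad_vs_load": [
        "sex", "education", "age_of_onset", "apoe", "family_history",
        "paternal_history", "maternal_history", "sibling_history", "same_town",
    ],
    "same_vs_different_town": [
        "sex", "education", "age_of_onset", "apoe", "apoe_e4_carrier",
        "family_history",
    ],
}

_UNKNOWN_LEVELS = {"unknown", None}


def _categorical_comparison(
    name: str, values: pd.Series, groups: pd.Series, levels: tuple[str, ...]
) -> GroupComparison:
    mask = values.notna() & ~values.isin(list(_UNKNOWN_LEVELS)) & groups.notna()
    tab = pd.crosstab(values[mask], groups[mask])
    tab = tab.reindex(columns=[g for g in levels if g in tab.columns], fill_value=0)
    summaries: dict[str, dict] = {}
    for g in tab.columns:
        total = int(tab[g].sum())
        summaries[str(g)] = {
            "n": total,
            "counts": {str(k): int(v) for k, v in tab[g].items()},
            "percent": {
                str(k): (100.0 * v / total if total else float("nan"))
                for k, v in tab[g].items()
            },
        }
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return GroupComparison(
            name, "none", None, None, summaries, note="fewer than 2x2 observed levels"
        )
    observed = tab.to_numpy()
    expected = stats.contingency.expected_freq(observed)
    if (expected == 0).any():
        return GroupComparison(
            name, "chi_square", None, None, summaries,
            note="skipped: zero expected cell count",
        )
    chi2, p, dof, _ = stats.chi2_contingency(observed, correction=False)
    return GroupComparison(name, "chi_square", float(chi2), float(p), summaries)


def _continuous_comparison(
    name: str, values: pd.Series, groups: pd.Series, levels: tuple[str, ...]
) -> GroupComparison:
    mask = values.notna() & groups.notna()
    summaries: dict[str, dict] = {}
    samples = []
    for g in levels:
        x = values[mask & (groups == g)].astype(float)
        summaries[str(g)] = {
            "n": int(len(x)),
            "mean": float(x.mean()) if len(x) else float("nan"),
            "sd": float(x.std(ddof=1)) if len(x) > 1 else float("nan"),
            "median": float(x.median()) if len(x) else float("nan"),
        }
        samples.append(x.to_numpy())
    usable = [s for s in samples if len(s)]
    if len(usable) < 2:
        return GroupComparison(
            name, "none", None, None, summaries, note="a group has no observations"
        )
    u, p = stats.mannwhitneyu(usable[0], usable[1], alternative="two-sided")
    return GroupComparison(name, "mann_whitney", float(u), float(p), summaries)


def describe_groups(
    cohort: CohortTable,
    grouping: str = "case_vs_control",
    variables: Sequence[str] | None = None,
) -> list[GroupComparison]:
    """Frequency/chi-square and mean±SD/Mann–Whitney group descriptives.

    Categorical variables are compared with Pearson chi-square (no
    continuity correction); ordinal/continuous ones are summarised as
    mean ± SD but tested with the rank-based Mann–Whitney U.
    """
    if grouping not in _GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; use one of {sorted(_GROUPINGS)}")
    group_col, levels = _GROUPINGS[grouping]
    frame = _derived_columns(cohort)
    groups = frame[group_col]
    if grouping == "eoad_vs_load":
        frame = frame[frame["status"] == "case"]
        groups = frame[group_col]
    n_levels = groups.dropna().nunique()
    if n_levels < 2:
        raise DegenerateTableError(
            f"grouping {grouping!r} yields {n_levels} group(s); need at least 2"
        )
    if variables is None:
        variables = _DEFAULT_VARIABLES[grouping]
    out = []
    for name in variables:
        if name == group_col:
            continue
        kind = _VARIABLE_KINDS.get(name)
        if kind is None:
            raise ValueError(f"unknown variable {name!r}")
        values = frame[name]
        if kind == "categorical":
            cmp_ = _categorical_comparison(name, values, groups, levels)
        else:
            cmp_ = _continuous_comparison(name, values, groups, levels)
        if cmp_.note:
            warnings.warn(f"{name}: {cmp_.note}", stacklevel=2)
        out.append(cmp_)
    return out


_APOE_GENOTYPES = ("e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4")
_HOMOZYGOTES = ("e2/e2", "e4/e4")


def apoe_by_birthplace(cohort: CohortTable) -> GroupComparison:
    """APOE genotype frequencies by parental-birthplace concordance.

    Returns the 6-genotype chi-square comparison between the same-town and
    different-town groups, with the pooled e2/e2 + e4/e4 homozygote fraction
    reported per group.
    """
    frame = _derived_columns(cohort)
    mask = frame["apoe"].notna() & frame["same_town"].isin(["same", "different"])
    if not mask.any():
        raise DegenerateTableError("no subject with both APOE and birthplace data")
    values = frame.loc[mask, "apoe"].map(normalize_apoe)
    groups = frame.loc[mask, "same_town"]
    cmp_ = _categorical_comparison("apoe", values, groups, ("same", "different"))
    for g, summary in cmp_.groups.items():
        counts = summary["counts"]
        total = summary["n"]
        hom = sum(counts.get(k, 0) for k in _HOMOZYGOTES)
        summary["homozygote_fraction"] = hom / total if total else float("nan")
    return cmp_
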