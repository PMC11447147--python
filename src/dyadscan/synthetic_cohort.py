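"""Generative cohort simulator for transmission-pattern analyses.

Subjects are simulated bottom-up: parental genotypes are drawn at
Hardy-Weinberg frequencies, offspring genotypes follow Mendelian
transmission (with sex-chromosome mechanics: sons get the paternal Y and a
single maternal X; daughters get the paternal X plus a maternal X), and
disease status for parents *and* offspring comes from the same logistic
liability.  That shared liability is what makes "parental history" an
informative proxy for parental genotype.

Remote consanguinity is modelled without pedigrees: for parents born in the
same town the offspring is, with probability equal to the configured
kinship coefficient F, autozygous at each autosomal locus (one parental
allele is drawn and duplicated), which yields the textbook homozygote
frequency q^2 + F q (1 - q) while preserving parent-offspring correlation.

Female X-linked expression is attenuated by ``lambda_x`` in heterozygotes
(1 = full expression, 0 = silenced), emulating X-inactivation.

All random draws go through one ``numpy`` Generator seeded from the config,
so a given config yields byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort_io import COLUMNS, CohortTable
from .errors import SimulationError, UnknownScenarioError

CHROMOSOMES = ("autosomal", "X", "Y")
MODES = ("dominant", "recessive", "additive")


@dataclass
class Locus:
    """One biallelic risk locus.

    ``gamma`` is the log-odds increment of the risk genotype; ``lambda_x``
    attenuates expression in heterozygous X-carrier females.  ``mode``
    applies to autosomal loci only (X/Y dosage is handled explicitly).
    """

    chromosome: str
    q: float
    mode: str = "dominant"
    gamma: float = 0.0
    lambda_x: float = 1.0

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"chromosome must be one of {CHROMOSOMES}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if not 0.0 <= self.lambda_x <= 1.0:
            raise ValueError("lambda_x must lie in [0, 1]")


@dataclass
class EndophenotypeModel:
    """Gaussian CSF marker model with history/autozygosity shift terms."""

    abeta42_mean: float = 520.0
    abeta42_sd: float = 190.0
    ttau_mean: float = 640.0
    ttau_sd: float = 340.0
    ptau_mean: float = 105.0
    ptau_sd: float = 60.0
    # sign convention: paternal history in females lowers t-tau and raises
    # p-tau; autozygosity raises p-tau and abeta42 but lowers t-tau
    paternal_female_ttau_shift: float = 0.0
    paternal_female_ptau_shift: float = 0.0
    autozygous_abeta_shift: float = 0.0
    autozygous_ttau_shift: float = 0.0
    autozygous_ptau_shift: float = 0.0


@dataclass
class SimConfig:
    """Full parameterisation of the generative transmission model."""

    n_cases: int
    n_controls: int
    loci: list[Locus] = field(default_factory=list)
    pi_same_town: float = 0.5
    kinship_phi: float = 0.0  # offspring inbreeding F for same-town parents
    beta0: float = -2.5
    beta_age: float = 0.07
    beta_sex_female: float = 0.2
    p_female: float = 0.62
    parent_death_age: tuple[float, float] = (77.0, 8.0)
    mother_death_age_offset: float = 4.0
    onset_base: tuple[float, float] = (72.0, 9.0)
    delta_autozygous: float = 0.0  # onset shift (years) for autozygous-risk
    endophenotype_model: EndophenotypeModel = field(default_factory=EndophenotypeModel)
    p_csf: float = 1.0  # fraction of cases carrying CSF measurements
    p_history_unknown: float = 0.0
    age_range: tuple[float, float] = (65.0, 95.0)
    n_towns: int = 50
    apoe_freqs: tuple[float, float, float] = (0.07, 0.77, 0.16)  # e2, e3, e4
    sibling_mean: float = 3.0
    sibling_dementia_rate: float = 0.05
    seed: int = 0
    max_batches: int = 60

    def __post_init__(self) -> None:
        for name in ("pi_same_town", "p_female", "p_csf", "p_history_unknown"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.kinship_phi <= 0.25:
            raise ValueError("kinship_phi must lie in [0, 0.25]")
        for name in ("parent_death_age", "onset_base"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} SD must be positive")
        if self.n_towns < 2:
            raise ValueError("n_towns must be at least 2")
        if abs(sum(self.apoe_freqs) - 1.0) > 1e-9:
            raise ValueError("apoe_freqs must sum to 1")


# ---------------------------------------------------------------------------
# vectorised genetic primitives (scalar spec operations wrap these)


def _parent_alleles_vec(
    locus: Locus, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray | None]:
    """HWE parental alleles: father (m, k_f) bool, mother (m, 2) or None."""
    q = locus.q
    if locus.chromosome == "autosomal":
        return rng.random((m, 2)) < q, rng.random((m, 2)) < q
    if locus.chromosome == "X":
        return rng.random((m, 1)) < q, rng.random((m, 2)) < q
    # Y: father hemizygous, mother carries nothing
    return rng.random((m, 1)) < q, None


def _transmit_vec(
    locus: Locus,
    father: np.ndarray,
    mother: np.ndarray | None,
    female: np.ndarray,
    ibd: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring risk-allele count (males are 0/1 at X and Y loci).

    ``ibd`` marks autozygous offspring (autosomal loci only): one parental
    allele is drawn at random and duplicated instead of the Mendelian draw.
    """
    m = father.shape[0]
    idx = np.arange(m)
    if locus.chromosome == "autosomal":
        pick_f = father[idx, rng.integers(0, 2, m)]
        pick_m = mother[idx, rng.integers(0, 2, m)]
        mendel = pick_f.astype(np.int8) + pick_m.astype(np.int8)
        from_father = rng.integers(0, 2, m).astype(bool)
        dup_f = father[idx, rng.integers(0, 2, m)]
        dup_m = mother[idx, rng.integers(0, 2, m)]
        dup = np.where(from_father, dup_f, dup_m)
        return np.where(ibd, 2 * dup.astype(np.int8), mendel)
    if locus.chromosome == "X":
        pick_m = mother[idx, rng.integers(0, 2, m)].astype(np.int8)
        daughters = pick_m + father[:, 0].astype(np.int8)
        sons = pick_m
        return np.where(female, daughters, sons)
    # Y: paternal allele to sons, absent (0) in daughters
    return np.where(female, 0, father[:, 0].astype(np.int8))


def _locus_contribution(
    locus: Locus, geno: np.ndarray, female: np.ndarray
) -> np.ndarray:
    """Per-subject log-odds contribution of one locus."""
    g = locus.gamma
    if locus.chromosome == "Y":
        return np.where(female, 0.0, g * (geno >= 1))
    if locus.chromosome == "X":
        male_term = g * (geno >= 1)
        female_term = np.where(
            geno == 2, g, np.where(geno == 1, locus.lambda_x * g, 0.0)
        )
        return np.where(female, female_term, male_term)
    if locus.mode == "dominant":
        return g * (geno >= 1)
    if locus.mode == "recessive":
        return g * (geno == 2)
    return g * geno  # additive


# ---------------------------------------------------------------------------
# scalar spec operations


def draw_parent_genotypes(
    config: SimConfig, same_town: bool, rng: np.random.Generator
) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Draw one (father, mother) genotype pair per configured locus.

    Genotypes are allele tuples (father has one allele at X and Y loci, the
    mother has none at Y loci).  Different-town pairs are plain HWE draws;
    the consanguinity excess for same-town pairs is applied at the offspring
    level (see :func:`generate_cohort`), giving offspring homozygosity
    q^2 + F q (1 - q).
    """
    out = []
    for locus in config.loci:
        fa, ma = _parent_alleles_vec(locus, 1, rng)
        father = tuple(int(v) for v in fa[0])
        mother = tuple(int(v) for v in ma[0]) if ma is not None else ()
        out.append((father, mother))
    return out


def transmit(
    parents: tuple[tuple[int, ...], tuple[int, ...]],
    offspring_sex: str,
    locus: Locus,
    rng: np.random.Generator,
):
    """Mendelian transmission for one subject at one locus.

    Returns the offspring risk-allele count, or ``"absent"`` for a Y locus
    in a female offspring.
    """
    father, mother = parents
    female = np.array([offspring_sex == "female"])
    if locus.chromosome == "Y" and offspring_sex == "female":
        return "absent"
    fa = np.array([father], dtype=bool)
    ma = np.array([mother], dtype=bool) if mother else None
    ibd = np.zeros(1, dtype=bool)
    geno = _transmit_vec(locus, fa, ma, female, ibd, rng)
    return int(geno[0])


def liability(
    genotypes: Sequence[int], sex: str, age: float, config: SimConfig
) -> float:
    """Disease probability for one subject under the logistic liability."""
    female = np.array([sex == "female"])
    logit = config.beta0 + config.beta_age * (age - 75.0) + (
        config.beta_sex_female if sex == "female" else 0.0
    )
    for locus, geno in zip(config.loci, genotypes):
        g = 0 if geno == "absent" else int(geno)
        logit += float(_locus_contribution(locus, np.array([g]), female)[0])
    return float(expit(logit))


# ---------------------------------------------------------------------------
# cohort generation


_APOE_LABELS = np.array(
    ["e2/e2", "e2/e3", "e2/e4", "e3/e3", "e3/e4", "e4/e4"], dtype=object
)
_APOE_CODE = {(0, 0): 0, (0, 1): 1, (0, 2): 2, (1, 1): 3, (1, 2): 4, (2, 2): 5}


def _apoe_genotypes(
    config: SimConfig, same: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    freqs = np.asarray(config.apoe_freqs)
    a1 = rng.choice(3, size=m, p=freqs)
    a2 = rng.choice(3, size=m, p=freqs)
    ibd = same & (rng.random(m) < config.kinship_phi)
    a2 = np.where(ibd, a1, a2)
    lo, hi = np.minimum(a1, a2), np.maximum(a1, a2)
    code = np.select(
        [(lo == 0) & (hi == 0), (lo == 0) & (hi == 1), (lo == 0) & (hi == 2),
         (lo == 1) & (hi == 1), (lo == 1) & (hi == 2)],
        [0, 1, 2, 3, 4],
        default=5,
    )
    return _APOE_LABELS[code]


def _simulate_batch(config: SimConfig, m: int, rng: np.random.Generator) -> dict:
    """Simulate ``m`` candidate subjects; returns column arrays + masks."""
    female = rng.random(m) < config.p_female
    # round at draw time so the >75 control mask agrees with the emitted value
    age = np.round(rng.uniform(config.age_range[0], config.age_range[1], m), 1)
    same = rng.random(m) < config.pi_same_town
    f_town = rng.integers(0, config.n_towns, m)
    offset = 1 + rng.integers(0, config.n_towns - 1, m)
    m_town = np.where(same, f_town, (f_town + offset) % config.n_towns)

    pd_mean, pd_sd = config.parent_death_age
    father_death = rng.normal(pd_mean, pd_sd, m)
    mother_death = rng.normal(pd_mean + config.mother_death_age_offset, pd_sd, m)

    logit_off = (
        config.beta0
        + config.beta_age * (age - 75.0)
        + config.beta_sex_female * female
    )
    logit_fa = config.beta0 + config.beta_age * (father_death - 75.0)
    logit_mo = (
        config.beta0
        + config.beta_age * (mother_death - 75.0)
        + config.beta_sex_female
    )
    autozygous_risk = np.zeros(m, dtype=bool)
    true_female = np.ones(m, dtype=bool)
    true_male = np.zeros(m, dtype=bool)
    for locus in config.loci:
        fa, ma = _parent_alleles_vec(locus, m, rng)
        if locus.chromosome == "autosomal":
            ibd = same & (rng.random(m) < config.kinship_phi)
        else:
            ibd = np.zeros(m, dtype=bool)
        geno = _transmit_vec(locus, fa, ma, female, ibd, rng)
        logit_off += _locus_contribution(locus, geno, female)
        # parents' own liabilities use their genotypes and sexes
        if locus.chromosome == "Y":
            logit_fa += _locus_contribution(locus, fa[:, 0].astype(np.int8), true_male)
        elif locus.chromosome == "X":
            logit_fa += _locus_contribution(locus, fa[:, 0].astype(np.int8), true_male)
            logit_mo += _locus_contribution(
                locus, ma.sum(axis=1).astype(np.int8), true_female
            )
        else:
            logit_fa += _locus_contribution(
                locus, fa.sum(axis=1).astype(np.int8), true_male
            )
            logit_mo += _locus_contribution(
                locus, ma.sum(axis=1).astype(np.int8), true_female
            )
        if locus.chromosome == "autosomal":
            autozygous_risk |= ibd & (geno == 2)

    affected = rng.random(m) < expit(logit_off)
    father_dem = rng.random(m) < expit(logit_fa)
    mother_dem = rng.random(m) < expit(logit_mo)
    pat_unknown = rng.random(m) < config.p_history_unknown
    mat_unknown = rng.random(m) < config.p_history_unknown

    onset_mean, onset_sd = config.onset_base
    onset = rng.normal(onset_mean, onset_sd, m)
    onset -= config.delta_autozygous * autozygous_risk
    onset = np.clip(onset, 40.0, None)
    onset = np.minimum(onset, age)

    apoe = _apoe_genotypes(config, same, m, rng)
    n_sib = rng.poisson(config.sibling_mean, m)
    sib_dem = rng.binomial(n_sib, config.sibling_dementia_rate)
    education = np.round(np.clip(rng.normal(4.5, 3.5, m), 0.0, 25.0), 1)

    has_csf = rng.random(m) < config.p_csf
    e = config.endophenotype_model
    pat_fem = female & father_dem & ~pat_unknown
    abeta = rng.normal(e.abeta42_mean, e.abeta42_sd, m)
    abeta += e.autozygous_abeta_shift * autozygous_risk
    ttau = rng.normal(e.ttau_mean, e.ttau_sd, m)
    ttau += e.paternal_female_ttau_shift * pat_fem
    ttau += e.autozygous_ttau_shift * autozygous_risk
    ptau = rng.normal(e.ptau_mean, e.ptau_sd, m)
    ptau += e.paternal_female_ptau_shift * pat_fem
    ptau += e.autozygous_ptau_shift * autozygous_risk
    abeta, ttau, ptau = (np.maximum(x, 5.0) for x in (abeta, ttau, ptau))
    age_at_lp = onset + rng.uniform(0.0, 2.0, m)

    return {
        "female": female,
        "age": age,
        "affected": affected,
        "onset": onset,
        "f_town": f_town,
        "m_town": m_town,
        "father_dem": father_dem,
        "mother_dem": mother_dem,
        "pat_unknown": pat_unknown,
        "mat_unknown": mat_unknown,
        "apoe": apoe,
        "n_sib": n_sib,
        "sib_dem": sib_dem,
        "education": education,
        "has_csf": has_csf,
        "abeta": abeta,
        "ttau": ttau,
        "ptau": ptau,
        "age_at_lp": age_at_lp,
    }


def _batch_to_rows(batch: dict, take: np.ndarray, is_case: bool) -> dict:
    """Column dict (schema order) for selected candidates of one status."""
    b = {k: v[take] for k, v in batch.items()}
    n = int(take.sum()) if take.dtype == bool else len(take)
    case_like = is_case
    age = b["age"]

    def history(dem: np.ndarray, unk: np.ndarray) -> np.ndarray:
        return np.where(unk, "unknown", np.where(dem, "yes", "no")).astype(object)
    rows = {
        "status": np.full(n, "case" if case_like else "control", dtype=object),
        "sex": np.where(b["female"], "female", "male").astype(object),
        "age_at_assessment": np.round(age, 1),
        "age_of_onset": np.round(b["onset"], 1) if case_like else np.full(n, np.nan),
        "education": b["education"],
        "year_of_birth": np.round(2024 - age).astype(float),
        "paternal_history": history(b["father_dem"], b["pat_unknown"]),
        "maternal_history": history(b["mother_dem"], b["mat_unknown"]),
        "father_birthplace": np.array(
            [f"town_{i:03d}" for i in b["f_town"]], dtype=object
        ),
        "mother_birthplace": np.array(
            [f"town_{i:03d}" for i in b["m_town"]], dtype=object
        ),
        "n_siblings": b["n_sib"].astype(float),
        "siblings_with_dementia": b["sib_dem"].astype(float),
        "apoe": b["apoe"],
    }
    if case_like:
        csf = b["has_csf"]
        rows["csf_abeta42"] = np.where(csf, np.round(b["abeta"], 1), np.nan)
        rows["csf_ttau"] = np.where(csf, np.round(b["ttau"], 1), np.nan)
        rows["csf_ptau"] = np.where(csf, np.round(b["ptau"], 1), np.nan)
        rows["age_at_lp"] = np.where(csf, np.round(b["age_at_lp"], 1), np.nan)
    else:
        for col in ("csf_abeta42", "csf_ttau", "csf_ptau", "age_at_lp"):
            rows[col] = np.full(n, np.nan)
    return rows


def generate_cohort(config: SimConfig) -> CohortTable:
    """Simulate a cohort with exactly the requested case/control counts.

    Candidates are drawn in batches; affected candidates become cases,
    unaffected candidates older than 75 become controls, until both quotas
    are met (in draw order, so output is deterministic for a given seed).
    """
    rng = np.random.default_rng(config.seed)
    batch_size = max(1000, 2 * (config.n_cases + config.n_controls))
    case_parts: list[dict] = []
    ctrl_parts: list[dict] = []
    got_cases = got_ctrls = 0
    for _ in range(config.max_batches):
        batch = _simulate_batch(config, batch_size, rng)
        case_mask = batch["affected"]
        ctrl_mask = ~batch["affected"] & (batch["age"] > 75.0)
        if got_cases < config.n_cases:
            idx = np.flatnonzero(case_mask)[: config.n_cases - got_cases]
            if len(idx):
                case_parts.append(_batch_to_rows(batch, idx, is_case=True))
                got_cases += len(idx)
        if got_ctrls < config.n_controls:
            idx = np.flatnonzero(ctrl_mask)[: config.n_controls - got_ctrls]
            if len(idx):
                ctrl_parts.append(_batch_to_rows(batch, idx, is_case=False))
                got_ctrls += len(idx)
        if got_cases >= config.n_cases and got_ctrls >= config.n_controls:
            break
    else:
        raise SimulationError(
            f"could not reach n_cases={config.n_cases}, n_controls="
            f"{config.n_controls} within {config.max_batches} batches "
            f"(got {got_cases}/{got_ctrls}); raise beta0 or the batch cap"
        )

    def _concat(parts: list[dict]) -> dict:
        keys = parts[0].keys()
        return {k: np.concatenate([p[k] for p in parts]) for k in keys}

    columns: dict[str, np.ndarray] = {}
    if case_parts and ctrl_parts:
        cases, ctrls = _concat(case_parts), _concat(ctrl_parts)
        columns = {k: np.concatenate([cases[k], ctrls[k]]) for k in cases}
    elif case_parts:
        columns = _concat(case_parts)
    else:
        columns = _concat(ctrl_parts)

    n = config.n_cases + config.n_controls
    frame = pd.DataFrame({"subject_id": [f"S{i:06d}" for i in range(n)]})
    for col in COLUMNS[1:]:
        frame[col] = columns[col]
    return CohortTable(
        frame,
        provenance={
            "source": "synthetic",
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "filters": [],
        },
    )


# ---------------------------------------------------------------------------
# scenario presets


def _null_config(n_cases: int, n_controls: int, seed: int) -> SimConfig:
    return SimConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        loci=[Locus("autosomal", q=0.2, mode="additive", gamma=0.0)],
        pi_same_town=0.5,
        kinship_phi=0.0,
        beta0=-1.5,
        beta_age=0.06,
        beta_sex_female=0.0,
        p_female=0.5,
        seed=seed,
    )


def _x_linked_config(n_cases: int, n_controls: int, seed: int) -> SimConfig:
    return SimConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        loci=[Locus("X", q=0.25, mode="dominant", gamma=4.0, lambda_x=0.05)],
        pi_same_town=0.5,
        beta0=-3.0,
        beta_age=0.06,
        beta_sex_female=0.2,
        p_female=0.5,
        seed=seed,
    )


def _y_linked_config(n_cases: int, n_controls: int, seed: int) -> SimConfig:
    return SimConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        loci=[Locus("Y", q=0.15, gamma=1.0)],
        pi_same_town=0.5,
        beta0=-1.6,
        beta_age=0.06,
        beta_sex_female=0.2,
        p_female=0.5,
        seed=seed,
    )


def _recessive_config(n_cases: int, n_controls: int, seed: int) -> SimConfig:
    return SimConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        loci=[Locus("autosomal", q=0.5, mode="recessive", gamma=2.5)],
        pi_same_town=0.58,
        kinship_phi=0.2,
        beta0=-2.2,
        beta_age=0.06,
        delta_autozygous=5.0,
        endophenotype_model=EndophenotypeModel(
            autozygous_abeta_shift=60.0,
            autozygous_ttau_shift=-80.0,
            autozygous_ptau_shift=25.0,
        ),
        seed=seed,
    )


def _paperlike_config(n_cases: int, n_controls: int, seed: int) -> SimConfig:
    # calibrated so parental-history frequencies land near the published
    # margins (controls ~4.7%/8.9%, cases ~13.5%/26.3%) and same-town ~58%
    return SimConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        loci=[
            Locus("autosomal", q=0.12, mode="additive", gamma=3.2),
            Locus("X", q=0.12, mode="dominant", gamma=1.8, lambda_x=0.3),
        ],
        pi_same_town=0.59,
        kinship_phi=0.03,
        beta0=-5.3,
        beta_age=0.07,
        beta_sex_female=0.7,
        p_female=0.63,
        parent_death_age=(76.0, 8.0),
        mother_death_age_offset=9.0,
        onset_base=(72.0, 9.0),
        delta_autozygous=1.5,
        endophenotype_model=EndophenotypeModel(
            paternal_female_ttau_shift=-95.0,
            paternal_female_ptau_shift=19.0,
            autozygous_abeta_shift=70.0,
            autozygous_ttau_shift=-70.0,
            autozygous_ptau_shift=15.0,
        ),
        p_csf=0.37,
        p_history_unknown=0.02,
        n_towns=60,
        seed=seed,
    )


_PRESETS = {
    "null": _null_config,
    "x_linked": _x_linked_config,
    "y_linked": _y_linked_config,
    "recessive_consanguinity": _recessive_config,
    "paperlike": _paperlike_config,
}


def scenario_preset(
    name: str,
    n_cases: int = 907,
    n_controls: int = 2183,
    seed: int = 0,
) -> SimConfig:
    """A documented parameter set for one analysis arm.

    Presets: ``null`` (no genetic effect), ``x_linked``, ``y_linked``,
    ``recessive_consanguinity`` and ``paperlike`` (targets the published
    cohort margins at n = 3090).
    """
    try:
        builder = _PRESETS[name]
    except KeyError:
        raise UnknownScenarioError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(_PRESETS))}"
        ) from None
    return builder(n_cases, n_controls, seed)


# ---------------------------------------------------------------------------
# regression-recovery fixtures


def linear_recovery_cohort(
    n: int,
    beta: dict[str, float],
    sigma: float,
    seed: int,
    outcome: str = "age_of_onset",
    intercept: float = 0.0,
) -> CohortTable:
    """Female-AD-with-CSF cohort whose ``outcome`` follows a known linear model.

    Predictors are drawn independently; the outcome column is overwritten
    with ``intercept + X @ beta + N(0, sigma)``.  Keys of ``beta`` must be
    the predictor names of the endophenotype models (indicator predictors
    use 0/1 coding).  Useful for exact-recovery and CI-coverage checks.
    """
    rng = np.random.default_rng(seed)
    pat = rng.random(n) < 0.3
    mat = rng.random(n) < 0.3
    town_same = rng.random(n) < 0.5
    age_at_lp = rng.normal(70.0, 5.0, n)
    education = np.clip(rng.normal(6.0, 3.0, n), 0, None)
    onset = rng.normal(70.0, 6.0, n)
    carrier = rng.random(n) < 0.4
    abeta = np.maximum(rng.normal(520.0, 150.0, n), 5.0)
    ttau = np.maximum(rng.normal(640.0, 250.0, n), 5.0)
    ptau = np.maximum(rng.normal(105.0, 50.0, n), 5.0)
    yob = np.round(rng.normal(1950.0, 8.0, n))

    design = {
        "paternal_history": pat.astype(float),
        "maternal_history": mat.astype(float),
        "same_town": town_same.astype(float),
        "age_at_lp": age_at_lp,
        "education": education,
        "age_of_onset": onset,
        "apoe_e4_carrier": carrier.astype(float),
        "csf_abeta42": abeta,
        "csf_ttau": ttau,
        "csf_ptau": ptau,
        "year_of_birth": yob,
    }
    y = intercept + rng.normal(0.0, sigma, n) if sigma > 0 else np.full(n, intercept)
    for name, b in beta.items():
        if name == outcome or name not in design:
            raise ValueError(f"bad beta term {name!r}")
        y = y + b * design[name]

    values = dict(design)
    values[outcome] = y
    frame = pd.DataFrame(
        {
            "subject_id": [f"R{i:06d}" for i in range(n)],
            "status": "case",
            "sex": "female",
            "age_at_assessment": np.maximum(values["age_of_onset"] + 2.0, 41.0),
            "age_of_onset": values["age_of_onset"],
            "education": values["education"],
            "year_of_birth": values["year_of_birth"],
            "paternal_history": np.where(pat, "yes", "no"),
            "maternal_history": np.where(mat, "yes", "no"),
            "father_birthplace": "town_a",
            "mother_birthplace": np.where(town_same, "town_a", "town_b"),
            "n_siblings": 2.0,
            "siblings_with_dementia": 0.0,
            "apoe": np.where(carrier, "e3/e4", "e3/e3"),
            "csf_abeta42": np.maximum(values["csf_abeta42"], 1e-3),
            "csf_ttau": np.maximum(values["csf_ttau"], 1e-3),
            "csf_ptau": np.maximum(values["csf_ptau"], 1e-3),
            "age_at_lp": values["age_at_lp"],
        }
    )
    return CohortTable(frame, provenance={"source": "linear_recovery", "filters": []})


def logistic_recovery_cohort(
    n: int,
    beta: dict[str, float],
    seed: int,
    intercept: float = 0.0,
) -> CohortTable:
    """Cohort whose case status follows a known logistic model.

    Recognised terms: ``sex_female``, ``age``, ``education``,
    ``apoe_e4_carrier``, ``same_town``.  The age covariate is written to
    ``age_of_onset`` for cases and ``age_at_assessment`` for controls,
    matching how the AD logistic model assembles its age column.
    """
    rng = np.random.default_rng(seed)
    female = rng.random(n) < 0.6
    age = rng.normal(75.0, 8.0, n)
    education = np.clip(rng.normal(5.0, 3.5, n), 0, None)
    carrier = rng.random(n) < 0.35
    town_same = rng.random(n) < 0.58
    design = {
        "sex_female": female.astype(float),
        "age": age,
        "education": education,
        "apoe_e4_carrier": carrier.astype(float),
        "same_town": town_same.astype(float),
    }
    logit = np.full(n, float(intercept))
    for name, b in beta.items():
        if name not in design:
            raise ValueError(f"bad beta term {name!r}")
        logit += b * design[name]
    case = rng.random(n) < expit(logit)

    frame = pd.DataFrame(
        {
            "subject_id": [f"L{i:06d}" for i in range(n)],
            "status": np.where(case, "case", "control"),
            "sex": np.where(female, "female", "male"),
            "age_at_assessment": age,
            "age_of_onset": np.where(case, age, np.nan),
            "education": education,
            "year_of_birth": np.round(2024 - age),
            "paternal_history": "no",
            "maternal_history": "no",
            "father_birthplace": "town_a",
            "mother_birthplace": np.where(town_same, "town_a", "town_b"),
            "n_siblings": 2.0,
            "siblings_with_dementia": 0.0,
            "apoe": np.where(carrier, "e3/e4", "e3/e3"),
            "csf_abeta42": np.nan,
            "csf_ttau": np.nan,
            "csf_ptau": np.nan,
            "age_at_lp": np.nan,
        }
    )
    return CohortTable(frame, provenance={"source": "logistic_recovery", "filters": []})
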