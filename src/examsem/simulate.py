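"""Monte Carlo model of one examination administered repeatedly.

A cohort of candidates with normally distributed true scores sits the same
examination several times; each administration adds fresh, independent
normal error.  Passing candidates (score ≥ pass mark) may then be selected
and re-examined, which restricts the ability range.  The point the model
makes assertable: selection collapses the test-retest *reliability* while
leaving the *SEM* essentially unchanged — reliability is a property of the
cohort as much as of the test, the SEM of the test alone.

The generative model is parameterised on the *observed*-score mean and SD:

    true  ~ Normal(mean, sd · sqrt(reliability))
    error ~ Normal(0,    sd · sqrt(1 − reliability))      per administration

so that Var(observed) = sd² and the between-administration correlation is
the design reliability.  Scores are not truncated to [0, 100]; the model is
unbounded and truncation would bias the SDs.

Every stochastic quantity has a closed-form expectation in
:func:`analytic_expectations`, derived from normal tail and one-sided
truncation formulas; the simulator is validated against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .ctt import sem_from_reliability

__all__ = [
    "SimulationConfig",
    "Cohort",
    "ConcordanceTable",
    "RestrictionReport",
    "AnalyticExpectations",
    "generate_cohort",
    "classify",
    "concordance",
    "restricted_retest_analysis",
    "analytic_expectations",
    "run_paper_experiment",
    "replicate",
]

#: Default configuration: 10,000 candidates, observed mean 50%, SD 10%,
#: reliability 0.9, pass mark 60%, three administrations.
DEFAULT_N_CANDIDATES = 10_000
DEFAULT_MEAN = 50.0
DEFAULT_SD = 10.0
DEFAULT_RELIABILITY = 0.9
DEFAULT_PASS_MARK = 60.0
DEFAULT_N_ADMINISTRATIONS = 3


@dataclass(frozen=True)
class SimulationConfig:
    """One examination sat ``n_administrations`` times by one cohort.

    ``observed_mean``/``observed_sd`` are in percentage points on the
    0-100 mark scale.  ``seed`` drives every random draw; each
    administration gets its own child stream, so any single administration
    is reproducible in isolation.
    """

    n_candidates: int = DEFAULT_N_CANDIDATES
    observed_mean: float = DEFAULT_MEAN
    observed_sd: float = DEFAULT_SD
    reliability: float = DEFAULT_RELIABILITY
    pass_mark: float = DEFAULT_PASS_MARK
    n_administrations: int = DEFAULT_N_ADMINISTRATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_candidates < 2:
            raise ValueError("n_candidates must be >= 2")
        if self.observed_sd <= 0:
            raise ValueError("observed_sd must be positive")
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError("reliability must be in [0, 1]")
        if self.n_administrations < 1:
            raise ValueError("n_administrations must be >= 1")

    @property
    def true_sd(self) -> float:
        return self.observed_sd * np.sqrt(self.reliability)

    @property
    def error_sd(self) -> float:
        return self.observed_sd * np.sqrt(1.0 - self.reliability)


@dataclass(frozen=True)
class Cohort:
    """Generated true scores plus one observed-score column per sitting."""

    true_scores: np.ndarray
    observed_scores: np.ndarray  # (n_candidates, n_administrations)
    config: SimulationConfig

    def administration(self, index: int) -> np.ndarray:
        if not 0 <= index < self.config.n_administrations:
            raise IndexError(
                f"administration {index} out of range "
                f"(0..{self.config.n_administrations - 1})"
            )
        return self.observed_scores[:, index]


@dataclass(frozen=True)
class ConcordanceTable:
    """2×2 pass/fail cross-classification between two administrations."""

    pass_pass: int
    pass_fail: int
    fail_pass: int
    fail_fail: int

    @property
    def n(self) -> int:
        return self.pass_pass + self.pass_fail + self.fail_pass + self.fail_fail

    @property
    def discordant(self) -> int:
        return self.pass_fail + self.fail_pass


@dataclass(frozen=True)
class RestrictionReport:
    """Re-test statistics within the selected (passing) sub-cohort."""

    n_selected: int
    restricted_sds: tuple[float, float]
    mean_restricted_sd: float
    retest_correlation: float
    sem: float


@dataclass(frozen=True)
class AnalyticExpectations:
    """Closed-form expectations for every simulated statistic."""

    pass_rate: float
    both_pass_rate: float
    full_correlation: float
    restricted_sd: float
    restricted_correlation: float
    sem: float


def _admin_rng(seed: int, stream: int) -> np.random.Generator:
    # stream 0: true scores; stream k>=1: administration k's errors
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Draw true scores and per-administration observed scores.

    Deterministic given ``config.seed``.  With reliability 1 every
    administration reproduces the true scores exactly.
    """
    true = _admin_rng(config.seed, 0).normal(
        config.observed_mean, config.true_sd, config.n_candidates
    )
    observed = np.empty((config.n_candidates, config.n_administrations))
    for k in range(config.n_administrations):
        errors = _admin_rng(config.seed, k + 1).normal(
            0.0, config.error_sd, config.n_candidates
        )
        observed[:, k] = true + errors
    return Cohort(true_scores=true, observed_scores=observed, config=config)


def classify(scores, pass_mark: float) -> np.ndarray:
    """Boolean pass vector; a score exactly at the mark passes."""
    return np.asarray(scores, dtype=float) >= pass_mark


def concordance(cohort: Cohort, admin_a: int, admin_b: int) -> ConcordanceTable:
    """Cross-classify pass/fail at the config pass mark for two sittings."""
    pa = classify(cohort.administration(admin_a), cohort.config.pass_mark)
    pb = classify(cohort.administration(admin_b), cohort.config.pass_mark)
    return ConcordanceTable(
        pass_pass=int(np.sum(pa & pb)),
        pass_fail=int(np.sum(pa & ~pb)),
        fail_pass=int(np.sum(~pa & pb)),
        fail_fail=int(np.sum(~pa & ~pb)),
    )


def restricted_retest_analysis(
    cohort: Cohort, selection_admin: int, retest_admins: tuple[int, int]
) -> RestrictionReport:
    """Re-test statistics among candidates passing the selection sitting.

    Reports the two re-test administrations' sample SDs, their arithmetic
    mean, the Pearson correlation between the two re-tests, and the SEM
    recovered from (mean restricted SD, re-test correlation).
    """
    a, b = retest_admins
    if len({selection_admin, a, b}) != 3:
        raise ValueError("selection and the two re-test administrations must differ")
    selected = classify(
        cohort.administration(selection_admin), cohort.config.pass_mark
    )
    if int(selected.sum()) < 2:
        raise ValueError("fewer than 2 candidates passed the selection sitting")
    x = cohort.administration(a)[selected]
    y = cohort.administration(b)[selected]
    sd_a = float(x.std(ddof=1))
    sd_b = float(y.std(ddof=1))
    mean_sd = 0.5 * (sd_a + sd_b)
    r = float(np.corrcoef(x, y)[0, 1])
    if 0.0 <= r <= 1.0:
        sem = sem_from_reliability(mean_sd, r)
    else:  # pragma: no cover - needs pathological data
        sem = mean_sd * float(np.sqrt(1.0 - r))
    return RestrictionReport(
        n_selected=int(selected.sum()),
        restricted_sds=(sd_a, sd_b),
        mean_restricted_sd=mean_sd,
        retest_correlation=r,
        sem=sem,
    )


def analytic_expectations(config: SimulationConfig) -> AnalyticExpectations:
    """Closed-form expectations under the generative model.

    With standardized cut ``a = (pass_mark − mean)/sd``:

    * pass rate = ``1 − Φ(a)``;
    * both-pass rate = the bivariate-normal orthant ``P(Z₁>a, Z₂>a)`` at
      inter-administration correlation equal to the reliability;
    * selection on one administration truncates that administration's
      standardized score to ``> a``; with hazard ``δ = φ(a)/(1 − Φ(a))``
      its variance shrinks by the factor ``v = 1 − δ(δ − a)``, and the
      true-score variance, which regresses on it with slope ``reliability``,
      becomes ``σ_T²(1 − reliability·(1 − v))``;
    * a fresh administration of the selected group then has variance
      ``Var(T|sel) + σ_E²`` and re-test correlation
      ``Var(T|sel)/(Var(T|sel) + σ_E²)``;
    * the SEM is exactly ``σ_E`` — untouched by selection.
    """
    a = (config.pass_mark - config.observed_mean) / config.observed_sd
    pass_rate = float(stats.norm.sf(a))
    rho = config.reliability
    # P(Z1 > a, Z2 > a) = P(Z1 < -a, Z2 < -a) by central symmetry
    if rho == 1.0:
        both = pass_rate
    else:
        both = float(
            stats.multivariate_normal(
                mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
            ).cdf([-a, -a])
        )
    delta = float(stats.norm.pdf(a) / stats.norm.sf(a))
    v = 1.0 - delta * (delta - a)
    var_true_sel = config.true_sd**2 * (1.0 - rho * (1.0 - v))
    var_err = config.error_sd**2
    var_obs_sel = var_true_sel + var_err
    restricted_corr = var_true_sel / var_obs_sel if var_obs_sel > 0 else 1.0
    return AnalyticExpectations(
        pass_rate=pass_rate,
        both_pass_rate=both,
        full_correlation=rho,
        restricted_sd=float(np.sqrt(var_obs_sel)),
        restricted_correlation=restricted_corr,
        sem=config.error_sd,
    )


def run_paper_experiment(config: SimulationConfig | None = None) -> dict:
    """One full selection-and-retest experiment, as a JSON-ready report.

    Generates the cohort, cross-classifies administrations 1 and 2 at the
    pass mark, then restricts to first-sitting passers and analyses their
    second and third sittings.  The full-sample SEM uses the first
    administration's SD with the administration-1/2 correlation; the
    restricted SEM comes from :func:`restricted_retest_analysis`.  The
    report is byte-for-byte reproducible from the seed.
    """
    if config is None:
        config = SimulationConfig()
    if config.n_administrations < 3:
        raise ValueError("the experiment needs at least 3 administrations")
    cohort = generate_cohort(config)
    first = cohort.administration(0)
    second = cohort.administration(1)
    table = concordance(cohort, 0, 1)
    restriction = restricted_retest_analysis(cohort, 0, (1, 2))
    full_sd = float(first.std(ddof=1))
    full_r = float(np.corrcoef(first, second)[0, 1])
    full_sem = sem_from_reliability(full_sd, full_r) if 0 <= full_r <= 1 else float(
        full_sd * np.sqrt(1 - full_r)
    )
    return {
        "config": asdict(config),
        "full_sample": {
            "mean": float(first.mean()),
            "sd": full_sd,
            "n_passed": table.pass_pass + table.pass_fail,
            "pass_fraction": (table.pass_pass + table.pass_fail) / table.n,
            "retest_correlation": full_r,
            "sem": full_sem,
        },
        "concordance": {
            "pass_pass": table.pass_pass,
            "pass_fail": table.pass_fail,
            "fail_pass": table.fail_pass,
            "fail_fail": table.fail_fail,
            "both_pass_fraction": table.pass_pass / table.n,
        },
        "restricted": {
            "n_selected": restriction.n_selected,
            "restricted_sds": list(restriction.restricted_sds),
            "mean_restricted_sd": restriction.mean_restricted_sd,
            "retest_correlation": restriction.retest_correlation,
            "sem": restriction.sem,
        },
    }


def _replicate_seed(base_seed: int, index: int) -> int:
    # stable per-replicate seeds below 2**31, independent of replicate count
    return int(
        np.random.SeedSequence((base_seed, index)).generate_state(1)[0] % (2**31)
    )


_SUMMARY_KEYS = (
    ("full_sample", "pass_fraction"),
    ("full_sample", "sd"),
    ("full_sample", "retest_correlation"),
    ("full_sample", "sem"),
    ("concordance", "both_pass_fraction"),
    ("restricted", "mean_restricted_sd"),
    ("restricted", "retest_correlation"),
    ("restricted", "sem"),
)


def replicate(config: SimulationConfig, n_replicates: int) -> dict:
    """Independent repeats of the experiment with derived seeds.

    Returns per-replicate reports plus, for each headline statistic, the
    mean and sample SD across replicates (SD 0.0 when ``n_replicates`` is
    1).  Seeds are derived deterministically from ``config.seed`` so the
    replicate set is itself reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    reports = []
    for i in range(n_replicates):
        cfg_i = SimulationConfig(
            **{**asdict(config), "seed": _replicate_seed(config.seed, i)}
        )
        reports.append(run_paper_experiment(cfg_i))
    summary = {}
    for section, key in _SUMMARY_KEYS:
        values = np.array([rep[section][key] for rep in reports])
        summary[f"{section}.{key}"] = {
            "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)) if n_replicates > 1 else 0.0,
        }
    return {"n_replicates": n_replicates, "summary": summary, "replicates": reports}


def report_to_json(report: dict) -> str:
    """Serialize a report with fixed key order and float precision."""
    return json.dumps(_round_floats(report, 10), sort_keys=True, indent=2)


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj
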