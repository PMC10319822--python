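"""End-to-end orchestration: per-assemblage analysis records and
randomisation experiments, with the cross-assemblage regressions.

`analyze` runs the full chain per assemblage — contest counts to
energy-loss web to Jacobian to normalised matrix — and collects critical
self-regulation, loop weights, asymmetry and hierarchy metrics into one
record, fitting an ordinary least squares regression of s* on the
maximum 2-link loop weight when three or more assemblages are supplied.

`randomization_experiment` manipulates one source matrix (full, weak or
minimal randomisation, or the two hierarchy restorations) many times,
recomputes the metrics for every replicate, and fits the ensemble
regressions of s* on pairwise asymmetry, on the 2-link loop weight and
on community asymmetry.  The source record is included in each
regression alongside its replicates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import asymmetry as asym
from . import feedback, randomization
from .contact_io import ContactData, connectance
from .energy_loss import CostParameters, NormalizedMatrix, energy_loss_web, jacobian, normalize
from .stability import critical_self_regulation, critical_self_regulation_normalized

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "AnalysisResult",
    "RandomizationResult",
    "analyze",
    "analyze_one",
    "randomization_experiment",
    "fit_regression",
]

RECORD_COLUMNS = [
    "assemblage_id",
    "S",
    "connectance",
    "s_star",
    "re_lambda_d",
    "w2max",
    "pairwise_asymmetry",
    "community_asymmetry",
    "win_index",
    "intransitivity_operational",
    "n_diag_estimated",
    "config_hash",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-wide settings: contest costs, diagonal fill, search limits."""

    costs: CostParameters = field(default_factory=CostParameters)
    diag_fill_factor: float = 0.1
    fill_mean_includes_zeros: bool = False
    exact_order_limit: int = asym.EXACT_ORDER_LIMIT
    tolerance: float = 1e-8
    seed: int | None = None

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:12]


def fit_regression(x: np.ndarray, y: np.ndarray) -> dict:
    """OLS of y on x with intercept: slope, intercept, R^2, p-value, n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:  # degenerate predictor (e.g. an invariant of the manipulation)
        return {"slope": float("nan"), "intercept": float(y.mean()),
                "r_squared": float("nan"), "p_value": float("nan"), "n": int(len(y))}
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r_squared": float(model.rsquared),
        "p_value": float(model.pvalues[1]),
        "n": int(model.nobs),
    }


def analyze_one(contacts: ContactData, config: AnalysisConfig | None = None) -> dict:
    """Run the full chain on one assemblage and return its analysis record."""
    if config is None:
        config = AnalysisConfig()
    web = energy_loss_web(contacts, config.costs)
    jac = jacobian(
        web,
        contacts.abundance,
        config.diag_fill_factor,
        fill_mean_includes_zeros=config.fill_mean_includes_zeros,
    )
    norm = normalize(jac)
    stab = critical_self_regulation(jac, config.tolerance)
    comm = asym.community_asymmetry(norm.abar, exact_limit=config.exact_order_limit,
                                    rng=np.random.default_rng(config.seed))
    record = {
        "assemblage_id": contacts.assemblage_id,
        "S": contacts.n_species,
        "connectance": connectance(contacts),
        "s_star": stab.s_star,
        "re_lambda_d": stab.re_lambda_d,
        "w2max": feedback.max_two_link_loop_weight(jac),
        "pairwise_asymmetry": asym.pairwise_asymmetry(norm.abar).value,
        "community_asymmetry": comm.value,
        "win_index": asym.win_index(contacts).value,
        "intransitivity_operational": asym.intransitivity_index(jac),
        "n_diag_estimated": int(jac.diag_estimated.sum()),
        "config_hash": config.hash(),
    }
    logger.debug("analysed %s: s*=%.4g w2max=%.4g", contacts.assemblage_id,
                 record["s_star"], record["w2max"])
    return record


@dataclass
class AnalysisResult:
    records: pd.DataFrame
    regression: dict | None  # s* on w2max, when >= 3 assemblages


def analyze(contact_sets: list[ContactData], config: AnalysisConfig | None = None) -> AnalysisResult:
    """Analyse a set of assemblages and regress s* on the 2-link loop weight."""
    if not contact_sets:
        raise ValueError("need at least one assemblage")
    if config is None:
        config = AnalysisConfig()
    records = []
    for contacts in contact_sets:
        try:
            records.append(analyze_one(contacts, config))
        except Exception as exc:
            raise RuntimeError(f"analysis failed for assemblage {contacts.assemblage_id!r}") from exc
    df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    regression = None
    if len(df) >= 3:
        regression = fit_regression(df["w2max"], df["s_star"])
    return AnalysisResult(df, regression)


def _matrix_metrics(norm_arr: np.ndarray, exact_limit: int, rng: np.random.Generator) -> dict:
    n = NormalizedMatrix([f"sp{i}" for i in range(norm_arr.shape[0])], norm_arr)
    stab = critical_self_regulation_normalized(n)
    return {
        "s_star": stab.s_star,
        "w2max": feedback.max_two_link_loop_weight(norm_arr),
        "pairwise_asymmetry": asym.pairwise_asymmetry(norm_arr).value,
        "community_asymmetry": asym.community_asymmetry(
            norm_arr, exact_limit=exact_limit, rng=rng
        ).value,
    }


@dataclass
class RandomizationResult:
    records: pd.DataFrame  # kind, replicate, s_star, w2max, asymmetries
    regressions: dict  # per kind: s* on pairwise, w2max, community
    loop_summary: pd.DataFrame  # per kind and loop length: median max weight


def randomization_experiment(
    source: ContactData | NormalizedMatrix,
    kinds: list[str],
    reps: int,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    loop_spectrum_sample: int = 50,
) -> RandomizationResult:
    """Manipulate one source matrix ``reps`` times per kind and summarise.

    The s* of every manipulated matrix comes from the normalised shortcut
    (exact for uniform diagonal -1).  Loop-weight spectra, being the most
    expensive metric, are computed on at most ``loop_spectrum_sample``
    replicates per kind and summarised as the median maximum per length.
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    if config is None:
        config = AnalysisConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    unknown = set(kinds) - set(randomization.MANIPULATIONS)
    if unknown:
        raise ValueError(f"unknown manipulation kinds: {sorted(unknown)}")

    if isinstance(source, ContactData):
        web = energy_loss_web(source, config.costs)
        jac = jacobian(web, source.abundance, config.diag_fill_factor,
                       fill_mean_includes_zeros=config.fill_mean_includes_zeros)
        norm = normalize(jac)
    else:
        norm = source
    # fail early on topology problems shared by all pair manipulations
    if any(k != "full" for k in kinds):
        randomization._reciprocal_pairs(norm.abar)

    rows = []
    spectra: dict[str, list[feedback.LoopWeightSpectrum]] = {}
    src_metrics = _matrix_metrics(norm.abar, config.exact_order_limit, rng)
    rows.append({"kind": "source", "replicate": 0, **src_metrics})
    spectra["source"] = [feedback.max_loop_weight_per_length(norm.abar)]
    for kind in kinds:
        fn = randomization.MANIPULATIONS[kind]
        spectra[kind] = []
        for rep in range(reps):
            manipulated = fn(norm, rng)
            arr = manipulated.abar
            rows.append(
                {"kind": kind, "replicate": rep + 1,
                 **_matrix_metrics(arr, config.exact_order_limit, rng)}
            )
            if rep < loop_spectrum_sample:
                spectra[kind].append(feedback.max_loop_weight_per_length(arr))
    records = pd.DataFrame(rows)

    regressions = {}
    for kind in kinds:
        sub = records[records["kind"].isin(["source", kind])]
        regressions[kind] = {
            "s_star_on_pairwise_asymmetry": fit_regression(
                sub["pairwise_asymmetry"], sub["s_star"]
            ),
            "s_star_on_w2max": fit_regression(sub["w2max"], sub["s_star"]),
            "s_star_on_community_asymmetry": fit_regression(
                sub["community_asymmetry"], sub["s_star"]
            ),
        }

    loop_rows = []
    for kind, specs in spectra.items():
        by_k: dict[int, list[float]] = {}
        for spec in specs:
            for k in spec.lengths:
                by_k.setdefault(k, []).append(spec.max_weight(k))
        for k, vals in sorted(by_k.items()):
            loop_rows.append(
                {"kind": kind, "k": k, "median_max_weight": float(np.median(vals)),
                 "n": len(vals)}
            )
    loop_summary = pd.DataFrame(loop_rows, columns=["kind", "k", "median_max_weight", "n"])
    logger.info("randomisation experiment: %d kinds x %d reps on %d species",
                len(kinds), reps, norm.abar.shape[0])
    return RandomizationResult(records, regressions, loop_summary)
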