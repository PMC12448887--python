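"""The study-style model suite.

Per-layer ALAAM fits, tie-subset models (same-/mixed-gender, kin/nonkin),
edge-directionality contrasts on reporter-only subnetworks (original vs
transposed tie matrices), and higher-order contagion variants (reciprocal,
indirect, closed-indirect, transitive).

Filters act on ties, not nodes: the node universe and covariate adjustment
set are unchanged across subset models, while degree-activity terms are
recomputed on the filtered network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import DIRECTED_LAYERS, LayerNetwork, PersonRecord
from .model import (
    DEFAULT_COVARIATES,
    AlaamResults,
    default_statistics,
    make_alaam,
)

logger = logging.getLogger(__name__)

HIGHER_ORDER_TERMS = (
    "reciprocal_contagion",
    "indirect_contagion",
    "closed_indirect_contagion",
    "transitive_contagion",
)


@dataclass(frozen=True)
class TieFilter:
    """A named, composable predicate over ties.

    The predicate receives (ego_id, alter_id, meta, records_by_id). The
    same-/mixed-gender pair and the kin/nonkin pair each partition the ties
    they are defined on.
    """

    name: str
    fn: Callable[[str, str, Mapping, Mapping[str, PersonRecord]], bool]

    def __call__(self, ego, alter, meta, by_id) -> bool:
        return self.fn(ego, alter, meta, by_id)

    def __and__(self, other: "TieFilter") -> "TieFilter":
        return TieFilter(
            f"{self.name}+{other.name}",
            lambda e, a, m, r: self.fn(e, a, m, r) and other.fn(e, a, m, r),
        )


def _gender_pair(m):
    return m.get("ego_gender"), m.get("alter_gender")


TIE_FILTERS: dict[str, TieFilter] = {
    "all": TieFilter("all", lambda e, a, m, r: True),
    "same_gender": TieFilter(
        "same_gender",
        lambda e, a, m, r: None not in _gender_pair(m)
        and m["ego_gender"] == m["alter_gender"]),
    "mixed_gender": TieFilter(
        "mixed_gender",
        lambda e, a, m, r: None not in _gender_pair(m)
        and m["ego_gender"] != m["alter_gender"]),
    "kin_only": TieFilter("kin_only", lambda e, a, m, r: m.get("kin") == 1),
    "nonkin_only": TieFilter("nonkin_only", lambda e, a, m, r: m.get("kin") == 0),
    "reporters_only": TieFilter(
        "reporters_only",
        lambda e, a, m, r: r[e].is_reporter == 1 and r[a].is_reporter == 1),
}


def apply_tie_filter(net: LayerNetwork, filt: TieFilter | str,
                     records: Sequence[PersonRecord]) -> LayerNetwork:
    """Network with only the ties passing the filter; node set unchanged
    (degrees are recomputed on the filtered ties)."""
    if isinstance(filt, str):
        filt = TIE_FILTERS[filt]
    by_id = {r.person_id: r for r in records}
    out = net.subset(lambda e, a, m: filt(e, a, m, by_id),
                     name=f"{net.name}[{filt.name}]")
    if out.n_ties == 0:
        raise ValueError(
            f"filter {filt.name!r} leaves no ties on layer {net.name!r}; "
            "fitting a contagion model to an empty tie set is meaningless")
    return out


@dataclass
class FitConfig:
    """Shared MCMC/model settings for a suite of fits.

    Per-model seeds are derived deterministically from ``seed`` in a fixed
    model order, so suite results are reproducible bit-for-bit.
    """

    seed: int
    covariates: Sequence[str] = DEFAULT_COVARIATES
    prior_sd: float = 10.0
    draws: int = 2000
    burn: int = 1000
    thin: int = 1
    aux_sweeps: int = 30


@dataclass
class ModelFit:
    name: str
    n_ties: int
    result: AlaamResults | None
    error: str | None = None


@dataclass
class ModelSuiteResult:
    """Fits per (layer x filter [x direction/term]) plus tie counts."""

    fits: dict[str, ModelFit]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            if fit.result is None:
                continue
            s = fit.result.summary().reset_index(names="parameter")
            s.insert(0, "model", name)
            s["n_ties"] = fit.n_ties
            rows.append(s)
        if not rows:
            return pd.DataFrame()
        return pd.concat(rows, ignore_index=True)

    def failures(self) -> dict[str, str]:
        return {k: v.error for k, v in self.fits.items() if v.error}

    def save(self, outdir) -> list[str]:
        """One summary CSV per model plus a combined frame; returns paths."""
        import os

        paths = []
        for name, fit in self.fits.items():
            if fit.result is None:
                continue
            path = os.path.join(outdir, f"model_{name}_summary.csv")
            fit.result.to_csv(summary_path=path)
            paths.append(path)
        combined = os.path.join(outdir, "suite_summary.csv")
        self.summary_frame().to_csv(combined, index=False)
        paths.append(combined)
        return paths


def _fit_one(name: str, net: LayerNetwork, records, config: FitConfig,
             seed: int, statistics=None) -> ModelFit:
    try:
        model = make_alaam(records, net, covariates=config.covariates,
                           statistics=statistics, prior_sd=config.prior_sd,
                           name=name)
        res = model.fit(draws=config.draws, burn=config.burn, thin=config.thin,
                        seed=seed, aux_sweeps=config.aux_sweeps)
        return ModelFit(name=name, n_ties=net.n_ties, result=res)
    except Exception as exc:  # suite continues, failures reported
        logger.warning("model %s failed: %s", name, exc)
        return ModelFit(name=name, n_ties=net.n_ties, result=None, error=str(exc))


def suite_model_plan(layers: Mapping[str, LayerNetwork]) -> list[tuple[str, str, str]]:
    """(model name, layer, filter) triples: base model per layer, gender
    subsets for every layer, kin subsets for the directed layers."""
    plan = []
    for layer in layers:
        plan.append((f"{layer}_all", layer, "all"))
    for layer in layers:
        for f in ("same_gender", "mixed_gender"):
            plan.append((f"{layer}_{f}", layer, f))
    for layer in layers:
        if layer in DIRECTED_LAYERS:
            for f in ("kin_only", "nonkin_only"):
                plan.append((f"{layer}_{f}", layer, f))
    return plan


def run_model_suite(layers: Mapping[str, LayerNetwork],
                    records: Sequence[PersonRecord],
                    config: FitConfig) -> ModelSuiteResult:
    """Fit the base model for each layer and every tie-subset variant.

    Base chatting/respect models condition on out- and in-degree; the
    undirected household model conditions on out-degree only (in-degree
    would duplicate it and proxy household size). Individual model failures
    are recorded and do not stop the suite.
    """
    rng = np.random.default_rng(config.seed)
    fits: dict[str, ModelFit] = {}
    for name, layer, filt in suite_model_plan(layers):
        seed = int(rng.integers(2 ** 31))
        net = layers[layer]
        try:
            sub = net if filt == "all" else apply_tie_filter(net, filt, records)
        except ValueError as exc:
            logger.warning("model %s skipped: %s", name, exc)
            fits[name] = ModelFit(name=name, n_ties=0, result=None, error=str(exc))
            continue
        fits[name] = _fit_one(name, sub, records, config, seed,
                              statistics=default_statistics(net.directed))
    return ModelSuiteResult(fits)


@dataclass
class DirectionalityResult:
    """Paired outgoing/incoming fits on the reporter-only subnetwork."""

    outgoing: ModelFit
    incoming: ModelFit
    comparison: pd.Series | None

    def summary_frame(self) -> pd.DataFrame:
        return ModelSuiteResult(
            {"outgoing": self.outgoing, "incoming": self.incoming}).summary_frame()


def edge_directionality_test(net: LayerNetwork,
                             records: Sequence[PersonRecord],
                             config: FitConfig) -> DirectionalityResult:
    """Compare direct-contagion posteriors on original (outgoing) vs
    transposed (incoming) tie matrices.

    Partial network sampling prevents non-reporters from having outgoing
    ties, so the analysis is confined to ties among reporters. The
    comparison reports the mean paired-draw difference, the share of paired
    draws where outgoing exceeds incoming, and the overlap of the two 95%
    credible intervals. Undirected layers are refused: transposition is the
    identity there.
    """
    if not net.directed:
        raise ValueError("edge-directionality test requires a directed layer")
    reporters = [r.person_id for r in records if r.is_reporter == 1]
    sub = net.restrict_nodes(reporters, name=f"{net.name}[reporters]")
    rec_sub = [r for r in records if r.is_reporter == 1]
    rng = np.random.default_rng(config.seed)
    seeds = [int(rng.integers(2 ** 31)) for _ in range(2)]
    stats = default_statistics(True)
    out_fit = _fit_one(f"{net.name}_outgoing", sub, rec_sub, config, seeds[0],
                       statistics=stats)
    in_fit = _fit_one(f"{net.name}_incoming", sub.transpose(), rec_sub, config,
                      seeds[1], statistics=stats)
    comparison = None
    if out_fit.result is not None and in_fit.result is not None:
        a = out_fit.result.draws["direct_contagion"].to_numpy()
        b = in_fit.result.draws["direct_contagion"].to_numpy()
        k = min(len(a), len(b))
        diff = a[:k] - b[:k]
        ci_a = np.quantile(a, [0.025, 0.975])
        ci_b = np.quantile(b, [0.025, 0.975])
        lo, hi = max(ci_a[0], ci_b[0]), min(ci_a[1], ci_b[1])
        span = max(ci_a[1], ci_b[1]) - min(ci_a[0], ci_b[0])
        comparison = pd.Series({
            "mean_diff": diff.mean(),
            "sd_diff": diff.std(ddof=1),
            "pct_outgoing_gt_incoming": 100.0 * (diff > 0).mean(),
            "ci_overlap": max(0.0, hi - lo) / span if span > 0 else 1.0,
        })
    return DirectionalityResult(out_fit, in_fit, comparison)


def higher_order_suite(net: LayerNetwork,
                       records: Sequence[PersonRecord],
                       config: FitConfig,
                       terms: Sequence[str] = HIGHER_ORDER_TERMS,
                       ) -> ModelSuiteResult:
    """Model variants each adding one higher-order contagion term (mutual
    dyads, two-paths, closed two-paths, transitive triads) to the base
    specification on a directed layer."""
    if not net.directed:
        raise ValueError("higher-order contagion terms require a directed layer")
    rng = np.random.default_rng(config.seed)
    fits: dict[str, ModelFit] = {}
    for term in terms:
        if term not in HIGHER_ORDER_TERMS:
            raise ValueError(f"unknown higher-order term {term!r}")
        seed = int(rng.integers(2 ** 31))
        name = f"{net.name}_{term}"
        stats = default_statistics(True) + [term]
        fits[name] = _fit_one(name, net, records, config, seed, statistics=stats)
    return ModelSuiteResult(fits)
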