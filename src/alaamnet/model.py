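"""Bayesian autologistic actor-attribute models (ALAAMs).

The ALAAM is the social-influence counterpart of the exponential random
graph model: the network is fixed and a binary node attribute y is modeled
jointly as

    P(Y = y | theta) = exp(theta' z(y)) / kappa(theta),

where z(y) collects sufficient statistics — attribute prevalence
("density"), degree-activity terms, covariate-activity terms, and contagion
terms counting ties / mutual dyads / two-paths / triangles whose relevant
endpoints both carry the attribute. The normalizing constant kappa(theta)
sums over all 2^n attribute vectors, so the posterior is doubly
intractable; :meth:`Alaam.fit` samples it with the exchange algorithm,
using sequential Gibbs simulation of auxiliary attribute vectors.

Usage follows the familiar model/results pattern::

    model = Alaam.from_records(records, network)
    res = model.fit(draws=2000, burn=1000, seed=42)
    print(res.summary())

Every statistic in scope is at most quadratic in y (the middle node of a
two-path or triangle contributes no attribute value), i.e. z_t(y) =
0.5 y' U_t y for a symmetric zero-diagonal integer matrix U_t, so change
statistics are sparse matrix-vector products and the Gibbs kernel reduces
to weighted neighbor sums. See ``docs/methods.md`` for the weight matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit, logsumexp

from . import _kernels
from .data import LayerNetwork, PersonRecord, records_to_dataframe

logger = logging.getLogger(__name__)

STRUCTURAL_TERMS = (
    "attribute_density",
    "out_degree_activity",
    "in_degree_activity",
    "direct_contagion",
    "reciprocal_contagion",
    "indirect_contagion",
    "closed_indirect_contagion",
    "transitive_contagion",
)
_HIGHER_ORDER = (
    "reciprocal_contagion",
    "indirect_contagion",
    "closed_indirect_contagion",
    "transitive_contagion",
)

EXACT_MAX_NODES = 20


@dataclass
class AlaamSpec:
    """Statistic list, covariate columns, and priors defining one ALAAM fit.

    ``statistics`` may contain ``"direct_contagion@name"`` entries referring
    to named subnetworks (e.g. the same-gender tie subset) supplied to the
    model; covariate-activity terms are implied by the columns of the
    exogenous design. Priors are independent normals per parameter.
    """

    statistics: list[str] = field(default_factory=lambda: ["attribute_density",
                                                           "direct_contagion"])
    covariates: list[str] = field(default_factory=list)
    prior_mean: float = 0.0
    prior_sd: float = 10.0


def default_statistics(directed: bool) -> list[str]:
    """The base conditioning set: prevalence, degree activity (in-degree only
    on directed layers, where it is distinct from out-degree), direct
    contagion."""
    stats = ["attribute_density", "out_degree_activity"]
    if directed:
        stats.append("in_degree_activity")
    stats.append("direct_contagion")
    return stats


def _quad_weight_matrix(term: str, net: LayerNetwork) -> sp.csr_matrix:
    """Symmetric zero-diagonal weight matrix U with z = 0.5 y'Uy."""
    a = net.adjacency().astype(np.float64)
    if term == "direct_contagion":
        u = a + a.T if net.directed else a
    elif term == "reciprocal_contagion":
        u = a.multiply(a.T)
    elif term == "indirect_contagion":
        t = (a @ a).tolil()
        t.setdiag(0)
        t = t.tocsr()
        u = t + t.T
    elif term == "closed_indirect_contagion":
        c = a.multiply(a @ a)
        u = c + c.T
    elif term == "transitive_contagion":
        p = a.multiply(a @ a.T)
        u = p + p.T
    else:  # pragma: no cover
        raise ValueError(term)
    u = sp.csr_matrix(u)
    u.eliminate_zeros()
    return u


class Alaam:
    """An ALAAM for a binary outcome on a fixed network layer.

    Parameters
    ----------
    outcome : array-like of 0/1, aligned to ``network.nodes``, or a pandas
        Series indexed by node id.
    network : LayerNetwork
        The layer carrying the contagion terms.
    exog : DataFrame, optional
        Numeric covariate design, one covariate-activity term per column,
        indexed by node id (or positionally aligned).
    statistics : list of str, optional
        Structural terms; defaults to :func:`default_statistics`. Entries of
        the form ``"direct_contagion@name"`` add a direct-contagion term on
        ``subnetworks[name]``.
    subnetworks : dict, optional
        Named tie subsets (same node universe as ``network``).
    prior_mean, prior_sd : float or array
        Independent normal prior per parameter. The default N(0, 10) is a
        minimally informative proper prior: wide enough to be dominated by
        the data yet keeping the exchange acceptance ratio well defined.
    """

    def __init__(
        self,
        outcome,
        network: LayerNetwork,
        exog: pd.DataFrame | None = None,
        statistics: Sequence[str] | None = None,
        subnetworks: Mapping[str, LayerNetwork] | None = None,
        prior_mean=0.0,
        prior_sd=10.0,
        name: str | None = None,
    ):
        self.network = network
        self.subnetworks = dict(subnetworks or {})
        self.name = name or network.name or "alaam"
        n = network.n

        if isinstance(outcome, pd.Series):
            outcome = outcome.reindex(list(network.nodes))
        y = np.asarray(outcome, dtype=float)
        if y.shape != (n,):
            raise ValueError(f"outcome must have length {n}")
        if np.isnan(y).any():
            raise ValueError("outcome contains missing values; restrict to "
                             "complete cases first (see Alaam.from_records)")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("outcome must be binary 0/1")
        self.endog = y.astype(np.int8)

        if exog is not None:
            if isinstance(exog, pd.DataFrame) and not isinstance(
                    exog.index, pd.RangeIndex):
                exog = exog.reindex(list(network.nodes))
            exog = pd.DataFrame(exog)
            if exog.isna().any().any():
                raise ValueError("exog contains missing values")
            if len(exog) != n:
                raise ValueError("exog not aligned to network nodes")
        self.exog = exog

        stats = list(statistics) if statistics is not None \
            else default_statistics(network.directed)
        for s in stats:
            base = s.split("@", 1)[0]
            if base not in STRUCTURAL_TERMS:
                raise ValueError(f"unknown statistic {s!r}")
            if "@" in s:
                if base != "direct_contagion":
                    raise ValueError("only direct_contagion supports @subnetwork")
                sub = s.split("@", 1)[1]
                if sub not in self.subnetworks:
                    raise ValueError(f"unknown subnetwork {sub!r}")
            if base == "in_degree_activity" and not network.directed:
                raise ValueError("in_degree_activity duplicates out-degree on an "
                                 "undirected layer; remove it")
            if base in _HIGHER_ORDER and not network.directed:
                raise ValueError(f"{base} requires a directed layer")
        self.statistics_names = stats
        self.param_names = stats + (list(self.exog.columns) if exog is not None else [])
        p = len(self.param_names)

        self.prior_mean = np.broadcast_to(np.asarray(prior_mean, dtype=float), (p,)).copy()
        self.prior_sd = np.broadcast_to(np.asarray(prior_sd, dtype=float), (p,)).copy()
        if (self.prior_sd <= 0).any():
            raise ValueError("prior_sd must be positive")

        self._compile()

    # -- compilation -------------------------------------------------------

    def _compile(self) -> None:
        net = self.network
        n, p = net.n, len(self.param_names)
        S = np.zeros((n, p))
        quads: list[tuple[int, sp.csr_matrix]] = []
        dout = net.out_degrees().astype(float)
        din = net.in_degrees().astype(float)
        for t, term in enumerate(self.statistics_names):
            base, _, subname = term.partition("@")
            if base == "attribute_density":
                S[:, t] = 1.0
            elif base == "out_degree_activity":
                S[:, t] = dout
            elif base == "in_degree_activity":
                S[:, t] = din
            else:
                src = self.subnetworks[subname] if subname else net
                if subname and src.nodes != net.nodes:
                    raise ValueError("subnetwork node universe differs from network")
                quads.append((t, _quad_weight_matrix(base, src)))
        if self.exog is not None:
            S[:, len(self.statistics_names):] = self.exog.to_numpy(dtype=float)
        self._static = S
        self._quads = quads

        # concatenated CSR arrays for the Gibbs kernel
        Q = len(quads)
        qptr = np.zeros((Q, n + 1), dtype=np.int64)
        idx_parts, wgt_parts = [], []
        offset = 0
        self._quad_tidx = np.array([t for t, _ in quads], dtype=np.int64)
        for q, (_, u) in enumerate(quads):
            qptr[q] = u.indptr.astype(np.int64) + offset
            idx_parts.append(u.indices.astype(np.int64))
            wgt_parts.append(u.data.astype(np.float64))
            offset += u.nnz
        self._qptr = qptr
        self._qidx = (np.concatenate(idx_parts) if idx_parts
                      else np.zeros(0, dtype=np.int64))
        self._qwgt = (np.concatenate(wgt_parts) if wgt_parts
                      else np.zeros(0, dtype=np.float64))

    @property
    def n(self) -> int:
        return self.network.n

    @property
    def k_params(self) -> int:
        return len(self.param_names)

    # -- statistics --------------------------------------------------------

    def statistics_vector(self, y=None) -> np.ndarray:
        """Sufficient statistics z(y) in ``param_names`` order."""
        yv = self.endog if y is None else np.asarray(y)
        yf = yv.astype(float)
        z = self._static.T @ yf
        for t, u in self._quads:
            z[t] = 0.5 * yf @ (u @ yf)
        return z

    def change_statistics(self, i: int, y=None) -> np.ndarray:
        """delta_i = z(y with y_i = 1) - z(y with y_i = 0), computed locally."""
        yv = (self.endog if y is None else np.asarray(y)).astype(float)
        d = self._static[i].copy()
        for t, u in self._quads:
            d[t] = u[i].toarray().ravel() @ yv
        return d

    def change_statistics_matrix(self, y=None) -> np.ndarray:
        """All change statistics stacked (n x p): the pseudolikelihood design."""
        yv = (self.endog if y is None else np.asarray(y)).astype(float)
        d = self._static.copy()
        for t, u in self._quads:
            d[:, t] = u @ yv
        return d

    # -- exact likelihood (small n) ----------------------------------------

    def _enumerate_states(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n
        if n > EXACT_MAX_NODES:
            raise ValueError(f"exact enumeration limited to n <= {EXACT_MAX_NODES}")
        states = np.arange(2 ** n, dtype=np.int64)
        Y = ((states[:, None] >> np.arange(n)) & 1).astype(float)
        Z = Y @ self._static
        for t, u in self._quads:
            Z[:, t] = 0.5 * np.einsum("ij,ij->i", Y, Y @ u.toarray())
        return Y, Z

    def exact_loglik(self, theta) -> float:
        """theta'z(y_obs) - log kappa(theta) by full enumeration (n <= 20)."""
        theta = np.asarray(theta, dtype=float)
        _, Z = self._enumerate_states()
        return float(theta @ self.statistics_vector() - logsumexp(Z @ theta))

    def exact_state_probs(self, theta) -> np.ndarray:
        """Probability of every attribute vector (bitmask order, n <= 20)."""
        theta = np.asarray(theta, dtype=float)
        _, Z = self._enumerate_states()
        logp = Z @ theta
        logp -= logsumexp(logp)
        return np.exp(logp)

    # -- simulation --------------------------------------------------------

    def _kernel_args(self, theta: np.ndarray):
        sdot = self._static @ theta
        qtheta = theta[self._quad_tidx]
        return sdot, qtheta, self._qptr, self._qidx, self._qwgt

    def simulate(self, theta, sweeps: int, seed: int | None = None,
                 init=None) -> np.ndarray:
        """Draw an attribute vector by ``sweeps`` full Gibbs passes.

        Each pass updates nodes sequentially from the exact full
        conditionals P(y_i = 1 | y_-i) = logistic(theta' delta_i). ``init``
        defaults to the observed outcome.
        """
        if sweeps < 1:
            raise ValueError("sweeps must be >= 1")
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.k_params,):
            raise ValueError("theta has wrong length")
        y = (self.endog.copy() if init is None
             else np.asarray(init, dtype=np.int8).copy())
        if seed is not None:
            _kernels.seed_rng(int(seed))
        _kernels.gibbs_sweeps(y, *self._kernel_args(theta), int(sweeps))
        return y

    def simulate_state_distribution(self, theta, sweeps: int, burn: int = 0,
                                    seed: int | None = None, init=None
                                    ) -> np.ndarray:
        """Empirical state frequencies over a long Gibbs run (n <= 16)."""
        if self.n > 16:
            raise ValueError("state recording limited to n <= 16")
        theta = np.asarray(theta, dtype=float)
        y = (self.endog.copy() if init is None
             else np.asarray(init, dtype=np.int8).copy())
        counts = np.zeros(2 ** self.n, dtype=np.int64)
        if seed is not None:
            _kernels.seed_rng(int(seed))
        _kernels.gibbs_state_counts(y, *self._kernel_args(theta),
                                    int(sweeps), int(burn), counts)
        return counts / counts.sum()

    # -- estimation --------------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[PersonRecord], network: LayerNetwork,
                     **kwargs) -> "Alaam":
        """Build a model from person records with encoded covariates,
        complete-case on the outcome. See :func:`make_alaam`."""
        return make_alaam(records, network, **kwargs)

    def fit_pseudolikelihood(self, ridge: float = 1e-6, maxiter: int = 50
                             ) -> np.ndarray:
        """Maximum pseudolikelihood estimate: logistic regression of y_i on
        the change statistics delta_i(y_obs). Used to initialize the MCMC
        and scale the proposal; not a substitute for the exchange sampler."""
        D = self.change_statistics_matrix()
        y = self.endog.astype(float)
        theta = np.zeros(self.k_params)
        for _ in range(maxiter):
            mu = expit(D @ theta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            H = D.T @ (D * w[:, None]) + ridge * np.eye(self.k_params)
            g = D.T @ (y - mu) - ridge * theta
            step = np.linalg.solve(H, g)
            theta += step
            if np.abs(step).max() < 1e-8:
                break
        if not np.isfinite(theta).all() or np.abs(theta).max() > 30:
            logger.warning("pseudolikelihood estimate ill-conditioned; using zeros")
            return np.zeros(self.k_params)
        return theta

    def _log_prior(self, theta: np.ndarray) -> float:
        return float(-0.5 * np.sum(((theta - self.prior_mean) / self.prior_sd) ** 2))

    def fit(
        self,
        draws: int = 2000,
        burn: int = 1000,
        thin: int = 1,
        seed: int | None = None,
        aux_sweeps: int = 30,
        scale: float | np.ndarray | None = None,
        adapt: bool = True,
        target_accept: float = 0.25,
        init: np.ndarray | str = "pseudolikelihood",
    ) -> "AlaamResults":
        """Sample the doubly-intractable posterior with the exchange algorithm.

        At each step a random-walk proposal theta' is accepted with
        probability min{1, exp((theta'-theta)'(z(y_obs) - z(y')))
        pi(theta')/pi(theta)}, where y' is an auxiliary attribute vector
        simulated from the model at theta' (``aux_sweeps`` Gibbs passes
        started from the observed vector). The diagonal proposal scale is
        adapted during burn-in toward ``target_accept``.
        """
        if seed is None:
            raise ValueError("seed is a mandatory argument")
        if draws < 1 or burn < 0 or thin < 1:
            raise ValueError("invalid draws/burn/thin")
        rng = np.random.default_rng(seed)
        p = self.k_params
        z_obs = self.statistics_vector()
        if not np.isfinite(z_obs).all():
            raise FloatingPointError(f"non-finite observed statistic: {z_obs}")

        if isinstance(init, str):
            theta = self.fit_pseudolikelihood() if init == "pseudolikelihood" \
                else np.zeros(p)
        else:
            theta = np.asarray(init, dtype=float).copy()

        if scale is None:
            # rough per-parameter scale from the pseudolikelihood Fisher info
            D = self.change_statistics_matrix()
            mu = expit(D @ theta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            H = D.T @ (D * w[:, None]) + 1e-6 * np.eye(p)
            step_sd = np.sqrt(np.clip(np.diag(np.linalg.inv(H)), 1e-6, 4.0))
        else:
            step_sd = np.broadcast_to(np.asarray(scale, dtype=float), (p,)).copy()
        factor = 1.0

        total = burn + draws
        out = np.empty((draws // thin if thin > 1 else draws, p))
        kept = 0
        log_prior = self._log_prior(theta)
        accepted_post = 0
        window_acc: list[int] = []
        for it in range(total):
            prop = theta + factor * step_sd * rng.standard_normal(p)
            y_aux = self.simulate(prop, sweeps=aux_sweeps,
                                  seed=int(rng.integers(2 ** 31)))
            z_aux = self.statistics_vector(y_aux)
            if not np.isfinite(z_aux).all():
                raise FloatingPointError("non-finite auxiliary statistic")
            lp_prop = self._log_prior(prop)
            logr = (prop - theta) @ (z_obs - z_aux) + lp_prop - log_prior
            acc = np.log(rng.uniform()) < logr
            if acc:
                theta, log_prior = prop, lp_prop
            if it < burn:
                if adapt:
                    window_acc.append(int(acc))
                    if len(window_acc) == 25:
                        rate = np.mean(window_acc)
                        factor *= float(np.exp(0.6 * (rate - target_accept)))
                        factor = float(np.clip(factor, 1e-3, 1e3))
                        window_acc = []
            else:
                accepted_post += int(acc)
                j = it - burn
                if j % thin == 0 and kept < out.shape[0]:
                    out[kept] = theta
                    kept += 1
        draws_df = pd.DataFrame(out[:kept], columns=self.param_names)
        return AlaamResults(
            model=self,
            draws=draws_df,
            acceptance_rate=accepted_post / draws,
            seed=seed,
            settings={"draws": draws, "burn": burn, "thin": thin,
                      "aux_sweeps": aux_sweeps, "proposal_factor": factor},
        )


def summarize_posterior(draws: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter posterior summary: mean, sd, central 95% interval, and
    the percentage of the posterior mass above zero ("% in favor of positive
    contagion" for contagion terms)."""
    q = draws.quantile([0.025, 0.975])
    return pd.DataFrame({
        "mean": draws.mean(),
        "sd": draws.std(ddof=1),
        "ci2.5%": q.loc[0.025],
        "ci97.5%": q.loc[0.975],
        "pct_positive": 100.0 * (draws > 0).mean(),
    })


class AlaamResults:
    """Posterior draws and summaries from :meth:`Alaam.fit`."""

    def __init__(self, model: Alaam, draws: pd.DataFrame, acceptance_rate: float,
                 seed: int, settings: dict):
        self.model = model
        self.draws = draws
        self.acceptance_rate = float(acceptance_rate)
        self.seed = seed
        self.settings = dict(settings)

    @property
    def params(self) -> pd.Series:
        return self.draws.mean()

    @property
    def sd(self) -> pd.Series:
        return self.draws.std(ddof=1)

    @property
    def pct_positive(self) -> pd.Series:
        return 100.0 * (self.draws > 0).mean()

    def credible_interval(self, level: float = 0.95) -> pd.DataFrame:
        a = (1 - level) / 2
        q = self.draws.quantile([a, 1 - a]).T
        q.columns = [f"ci{100 * a:g}%", f"ci{100 * (1 - a):g}%"]
        return q

    def ess(self) -> pd.Series:
        import arviz as az

        ds = az.convert_to_dataset(self.draws.to_numpy()[None, :, :])
        vals = az.ess(ds)["x"].values
        return pd.Series(vals, index=self.draws.columns)

    def summary(self) -> pd.DataFrame:
        tab = summarize_posterior(self.draws)
        try:
            tab["ess"] = self.ess()
        except Exception:  # pragma: no cover - diagnostics only
            pass
        return tab

    def plot_posterior(self, params: Sequence[str] | None = None, bins: int = 40):
        """Histogram grid of marginal posteriors (minimal diagnostic plot)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        params = list(params) if params is not None else list(self.draws.columns)
        fig, axes = plt.subplots(1, len(params), figsize=(3 * len(params), 2.5),
                                 squeeze=False)
        for ax, name in zip(axes[0], params):
            ax.hist(self.draws[name], bins=bins, color="steelblue")
            ax.axvline(0.0, color="k", lw=0.8)
            ax.set_title(name, fontsize=8)
        fig.tight_layout()
        return fig

    def to_csv(self, draws_path=None, summary_path=None) -> None:
        if draws_path is not None:
            self.draws.to_csv(draws_path, index=False)
        if summary_path is not None:
            self.summary().to_csv(summary_path)

    def __repr__(self) -> str:
        return (f"<AlaamResults {self.model.name}: {len(self.draws)} draws, "
                f"{self.model.k_params} params, "
                f"acceptance {self.acceptance_rate:.2f}>")


# ---------------------------------------------------------------------------
# construction from records
# ---------------------------------------------------------------------------

DEFAULT_COVARIATES = ("gender", "education", "wealth_rank", "village")


def build_design(records: Sequence[PersonRecord],
                 covariates: Sequence[str] = DEFAULT_COVARIATES) -> pd.DataFrame:
    """Numeric covariate design indexed by person_id.

    gender -> woman indicator; education -> indicators with "none" as the
    reference; village -> indicators with the first (sorted) village as the
    reference; wealth_rank and age enter as scores.
    """
    df = records_to_dataframe(records)
    cols = {}
    for cov in covariates:
        if cov == "gender":
            cols["gender_woman"] = (df["gender"] == "woman").astype(float)
        elif cov == "education":
            from .data import EDUCATION_LEVELS

            for level in EDUCATION_LEVELS[1:]:
                key = "education_" + level.replace(" ", "_")
                cols[key] = (df["education"] == level).astype(float)
        elif cov == "village":
            for v in sorted(df["village"].unique())[1:]:
                cols[f"village_{v}"] = (df["village"] == v).astype(float)
        elif cov in ("wealth_rank", "age"):
            cols[cov] = df[cov].astype(float)
        else:
            cols[cov] = df[cov].astype(float)
    return pd.DataFrame(cols, index=df.index)


def make_alaam(records: Sequence[PersonRecord], network: LayerNetwork,
               covariates: Sequence[str] = DEFAULT_COVARIATES,
               statistics: Sequence[str] | None = None,
               subnetworks: Mapping[str, LayerNetwork] | None = None,
               prior_sd: float = 10.0, name: str | None = None) -> Alaam:
    """Build an :class:`Alaam` from person records, complete-case on the
    outcome (nodes with a missing outcome are dropped from the node universe
    with a logged count, and the network restricted accordingly)."""
    outcome = pd.Series({r.person_id: r.ipvaw_accept for r in records})
    complete = outcome.dropna()
    if len(complete) < len(outcome):
        logger.info("dropping %d nodes with missing outcome",
                    len(outcome) - len(complete))
        keep = set(complete.index)
        network = network.restrict_nodes(keep)
        if subnetworks:
            subnetworks = {k: v.restrict_nodes(keep) for k, v in subnetworks.items()}
        records = [r for r in records if r.person_id in keep]
    exog = build_design(records, covariates) if covariates else None
    return Alaam(complete.astype(int), network, exog=exog, statistics=statistics,
                 subnetworks=subnetworks, prior_sd=prior_sd, name=name)
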