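"""Longitudinal Gaussian-graphical-model inference.

The dynamical (time-weighted) correlation of each subject's complete
trajectories is pooled over subjects, shrunk toward the identity with a
data-driven intensity, and inverted to partial correlations.  Edge p values
come from the null density of a correlation coefficient with an effective
degree-of-freedom parameter fitted to the observed partial-correlation
distribution; an edge additionally needs a significant plain Pearson
correlation (the dual-significance rule) unless that gate is disabled.

The module follows the Model/Results idiom: build a :class:`DynamicalGGM`
from a complete, log2-scale dataset, call :meth:`~DynamicalGGM.fit`, and
extract networks from the returned :class:`GGMResults`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .errors import ConfigError, DomainError, NumericError
from .study import ProfileDataset, StudyDesign


# ---------------------------------------------------------------------------
# time weights


@dataclass(frozen=True)
class TimeWeights:
    """Trapezoid quadrature weights over an ordered time grid, normalised to 1."""

    times: tuple[float, ...]
    w: np.ndarray

    @property
    def n(self) -> int:
        return len(self.times)


def time_weights(times) -> TimeWeights:
    """Trapezoid weights: end points (gap)/2, interior (t_{k+1}−t_{k−1})/2."""
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise DomainError("time_weights needs at least 2 time points")
    if np.any(np.diff(t) <= 0):
        raise DomainError("times must be strictly increasing")
    raw = np.empty(t.size)
    raw[0] = (t[1] - t[0]) / 2.0
    raw[-1] = (t[-1] - t[-2]) / 2.0
    if t.size > 2:
        raw[1:-1] = (t[2:] - t[:-2]) / 2.0
    return TimeWeights(tuple(t), raw / raw.sum())


def _blockwise_weights(design: StudyDesign, tp_indices) -> np.ndarray:
    """Trapezoid weights per block on block clocks, jointly normalised.

    Each block is its own integration domain; weighting across the
    between-block break would give the boundary samples spurious mass.
    """
    raw = np.zeros(len(tp_indices))
    for block in (1, 2):
        pos = [i for i, t in enumerate(tp_indices) if design.tp(t).block == block]
        if not pos:
            continue
        clocks = [design.tp(tp_indices[i]).clock_min for i in pos]
        if len(pos) == 1:
            raw[pos[0]] = np.mean(np.diff(clocks)) if len(clocks) > 1 else 1.0
            continue
        tw = time_weights(clocks)
        span = clocks[-1] - clocks[0]
        raw[pos] = tw.w * span  # undo per-block normalisation: raw trapezoid mass
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# null model


@dataclass(frozen=True)
class NullModel:
    """Null density of a correlation coefficient, f0(r; kappa) ∝ (1−r²)^((κ−3)/2)."""

    kappa: float

    def logpdf(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        k = self.kappa
        return (
            (k - 3.0) / 2.0 * np.log1p(-(r**2))
            + special.gammaln(k / 2.0)
            - 0.5 * math.log(math.pi)
            - special.gammaln((k - 1.0) / 2.0)
        )

    def p_value(self, r) -> np.ndarray:
        """Two-sided P(|R0| ≥ |r|): R0² ~ Beta(1/2, (κ−1)/2)."""
        r = np.asarray(r, dtype=float)
        return special.betainc((self.kappa - 1.0) / 2.0, 0.5, 1.0 - r**2)


def fit_null_kappa(pcor_values) -> NullModel:
    """Maximum-likelihood effective-degrees-of-freedom fit to observed pcors."""
    r = np.asarray(pcor_values, dtype=float)
    if r.size < 50:
        raise DomainError("fit_null_kappa needs at least 50 off-diagonal values")
    if np.any((r <= -1.0) | (r >= 1.0)):
        raise DomainError("partial correlations must lie strictly in (-1, 1)")
    s = float(np.sum(np.log1p(-(r**2))))
    n = r.size

    def nll(log_km1: float) -> float:
        k = 1.0 + math.exp(log_km1)
        return -(
            (k - 3.0) / 2.0 * s
            + n * (special.gammaln(k / 2.0) - special.gammaln((k - 1.0) / 2.0))
        )

    res = optimize.minimize_scalar(
        nll, bounds=(math.log(1e-3), math.log(1e7)), method="bounded",
        options={"xatol": 1e-10},
    )
    return NullModel(kappa=1.0 + math.exp(float(res.x)))


def fit_null_kappa_trimmed(
    pcor_values, trim_alpha: float = 0.05, max_iter: int = 50
) -> NullModel:
    """Robust null fit: truncated MLE over the central bulk.

    Observed partial correlations are a mixture of a null bulk and a signal
    tail; a plain MLE over everything overstates the null width.  Here kappa
    is fitted by maximum likelihood of the null density truncated to
    |r| <= c, where c is the (1 − trim_alpha) null quantile of the current
    fit, iterating until kappa is stable.  The truncation term keeps the
    estimate unbiased under a pure null while the signal tail (which lives
    beyond c) no longer drags kappa down.
    """
    r = np.abs(np.asarray(pcor_values, dtype=float))
    null = fit_null_kappa(r)
    kappa = null.kappa
    for _ in range(max_iter):
        c2 = float(special.betaincinv(0.5, (kappa - 1.0) / 2.0, 1.0 - trim_alpha))
        kept = r**2 <= c2
        n = int(kept.sum())
        if n < 50:
            break
        s = float(np.sum(np.log1p(-(r[kept] ** 2))))

        def nll(log_km1: float) -> float:
            k = 1.0 + math.exp(log_km1)
            mass = float(special.betainc(0.5, (k - 1.0) / 2.0, c2))
            if mass <= 0.0:
                return np.inf
            return -(
                (k - 3.0) / 2.0 * s
                + n * (special.gammaln(k / 2.0) - special.gammaln((k - 1.0) / 2.0))
                - n * math.log(mass)
            )

        res = optimize.minimize_scalar(
            nll, bounds=(math.log(1e-3), math.log(1e7)), method="bounded",
            options={"xatol": 1e-10},
        )
        new_kappa = 1.0 + math.exp(float(res.x))
        if abs(new_kappa - kappa) <= 1e-4 * kappa:
            kappa = new_kappa
            break
        kappa = new_kappa
    return NullModel(kappa=kappa)


# ---------------------------------------------------------------------------
# the shrinkage estimate


@dataclass
class ShrinkageEstimate:
    """Dynamical correlation, shrinkage intensity and partial correlations."""

    uids: list[str]
    R: np.ndarray
    lambda_star: float
    R_shrunk: np.ndarray
    pcor: np.ndarray
    n_eff: int


def _pcor_from_corr(R: np.ndarray) -> np.ndarray:
    omega = np.linalg.inv(R)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


class DynamicalGGM:
    """Longitudinal GGM model over a complete log2-scale dataset.

    Parameters
    ----------
    dataset : ProfileDataset
        log2-transformed, imputed-complete over the chosen grid.
    uids, subjects, tps : optional restrictions of the estimation grid.
    """

    def __init__(self, dataset: ProfileDataset, uids=None, subjects=None, tps=None):
        if dataset.transform_tag != "log2":
            raise DomainError("DynamicalGGM expects a log2-transformed dataset")
        ds = dataset
        if uids is not None or subjects is not None or tps is not None:
            ds = ds.subset(subjects=subjects, tps=tps, uids=uids)
        self.dataset = ds
        self.uids = list(ds.uids)
        self.subjects = list(ds.design.subjects)
        self.tp_indices = list(ds.design.tp_indices)
        if len(self.uids) < 2 or len(self.subjects) < 2 or len(self.tp_indices) < 3:
            raise DomainError("need >= 2 metabolites, >= 2 subjects and >= 3 time points")
        wide = ds.values
        if wide.isna().to_numpy().any():
            raise DomainError("DynamicalGGM requires complete (imputed) data")
        # X[s] is (T x p)
        self._X = np.stack(
            [wide.xs(s, level="subject").loc[self.tp_indices].to_numpy() for s in self.subjects]
        )
        self.w = _blockwise_weights(ds.design, self.tp_indices)

    # -- estimation ------------------------------------------------------

    def _pooled_dynamical_cov(self) -> np.ndarray:
        w = self.w
        C = np.zeros((len(self.uids),) * 2)
        self._Xc = np.empty_like(self._X)
        for s in range(len(self.subjects)):
            X = self._X[s]
            mu = w @ X
            Xc = X - mu
            self._Xc[s] = Xc
            C += Xc.T @ (Xc * w[:, None])
        return C / len(self.subjects)

    def _lambda_star(self, C: np.ndarray, R: np.ndarray) -> float:
        S = len(self.subjects)
        d = np.sqrt(np.diag(C))
        Z = self._Xc / d  # standardized residuals, (S, T, p)
        Zf = Z.reshape(-1, Z.shape[2])
        omega = np.tile(self.w / S, S)
        h = float(np.sum(omega**2))
        M1 = Zf.T @ (Zf * omega[:, None])  # weighted mean products
        E2 = (Zf**2).T @ ((Zf**2) * omega[:, None])
        var_r = h / (1.0 - h) * (E2 - M1**2)
        iu = np.triu_indices(len(self.uids), k=1)
        denom = float(np.sum(R[iu] ** 2))
        if denom == 0.0:
            return 1.0
        return float(np.clip(np.sum(var_r[iu]) / denom, 0.0, 1.0))

    def fit(self, lambda_: float | None = None, fit_kappa: bool = True) -> "GGMResults":
        """Estimate R, the shrinkage intensity, partial correlations and p values.

        ``lambda_`` forces the shrinkage intensity (None = data-driven).
        """
        C = self._pooled_dynamical_cov()
        d = np.sqrt(np.diag(C))
        if np.any(d <= 0):
            raise NumericError("zero-variance metabolite in the estimation grid")
        R = C / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        lam = self._lambda_star(C, R) if lambda_ is None else float(lambda_)
        if not 0.0 <= lam <= 1.0:
            raise ConfigError("lambda must lie in [0, 1]")
        R_shrunk = lam * np.eye(len(self.uids)) + (1.0 - lam) * R
        try:
            pcor = _pcor_from_corr(R_shrunk)
        except np.linalg.LinAlgError:
            raise NumericError(
                "singular correlation matrix at lambda = 0; refit with a floor "
                "lambda_ >= 1e-6"
            ) from None
        est = ShrinkageEstimate(
            uids=list(self.uids),
            R=R,
            lambda_star=lam,
            R_shrunk=R_shrunk,
            pcor=pcor,
            n_eff=len(self.subjects) * len(self.tp_indices),
        )
        # plain pooled Pearson correlation, for the dual-significance gate
        flat = self._X.reshape(-1, self._X.shape[2])
        R_plain = np.corrcoef(flat, rowvar=False)
        null = None
        if fit_kappa:
            iu = np.triu_indices(len(self.uids), k=1)
            vals = np.clip(pcor[iu], -1 + 1e-12, 1 - 1e-12)
            if vals.size >= 50:
                null = fit_null_kappa_trimmed(vals)
        return GGMResults(self, est, R_plain, null)


class GGMResults:
    """Fitted longitudinal GGM: estimates, null model and network extraction."""

    def __init__(
        self,
        model: DynamicalGGM,
        estimate: ShrinkageEstimate,
        R_plain: np.ndarray,
        null: NullModel | None,
    ):
        self.model = model
        self.estimate = estimate
        self.R_plain = R_plain
        self.null = null

    @property
    def uids(self) -> list[str]:
        return self.estimate.uids

    @property
    def pcor(self) -> np.ndarray:
        return self.estimate.pcor

    @property
    def lambda_star(self) -> float:
        return self.estimate.lambda_star

    def pearson_p(self) -> np.ndarray:
        """Two-sided correlation-test p values on the pooled observations."""
        n = self.estimate.n_eff
        r = np.clip(self.R_plain, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * sps.t.sf(np.abs(t), n - 2)
        np.fill_diagonal(p, 0.0)
        return p

    def pcor_p(self) -> np.ndarray:
        if self.null is None:
            raise NumericError("no null model fitted (fit_kappa=False or too few pairs)")
        r = np.clip(self.pcor, -1 + 1e-12, 1 - 1e-12)
        p = np.asarray(self.null.p_value(r))
        np.fill_diagonal(p, 0.0)
        return p

    def summary(self) -> str:
        est = self.estimate
        p = len(est.uids)
        lines = [
            "Longitudinal Gaussian graphical model",
            "=" * 48,
            f"metabolites:          {p}",
            f"subjects:             {len(self.model.subjects)}",
            f"time points:          {len(self.model.tp_indices)}",
            f"pooled observations:  {est.n_eff}",
            f"shrinkage lambda*:    {est.lambda_star:.4f}",
        ]
        if self.null is not None:
            lines.append(f"null kappa:           {self.null.kappa:.1f}")
        iu = np.triu_indices(p, k=1)
        lines.append(
            f"|pcor| off-diagonal:  median {np.median(np.abs(est.pcor[iu])):.4f}, "
            f"max {np.max(np.abs(est.pcor[iu])):.4f}"
        )
        return "\n".join(lines)

    # -- network extraction ---------------------------------------------

    def network(
        self,
        mode: str = "cutoff",
        cutoff: float = 0.12,
        correction: str = "bonferroni",
        alpha: float = 0.05,
        require_pearson: bool = True,
        absolute: bool = False,
    ) -> "GgmNetwork":
        """Extract the edge set as a :class:`GgmNetwork`.

        ``mode="cutoff"``: edge iff signed pcor ≥ cutoff (or |pcor| ≥ cutoff
        with ``absolute=True``).  ``mode="significance"``: edge iff the pcor
        p value survives ``correction`` ∈ {raw5, bonferroni, fdr} over the
        p(p−1)/2 tests and, when ``require_pearson``, the Pearson correlation
        test has p < 0.05.
        """
        est = self.estimate
        p = len(est.uids)
        iu = np.triu_indices(p, k=1)
        if mode == "cutoff":
            if not -1.0 <= cutoff <= 1.0:
                raise ConfigError("cutoff must lie in [-1, 1]")
            vals = np.abs(est.pcor) if absolute else est.pcor
            keep = vals[iu] >= cutoff
            p_pcor = self.pcor_p() if self.null is not None else None
        elif mode == "significance":
            p_pcor = self.pcor_p()
            pv = p_pcor[iu]
            m = pv.size
            if correction == "raw5":
                sig = pv < alpha
            elif correction == "bonferroni":
                sig = pv < alpha / m
            elif correction == "fdr":
                from .stats import adjust_bh

                sig = adjust_bh(pv) < alpha
            else:
                raise ConfigError(f"unknown correction {correction!r}")
            keep = sig
        else:
            raise ConfigError(f"unknown mode {mode!r}")

        p_pearson = self.pearson_p()
        if mode == "significance" and require_pearson:
            keep = keep & (p_pearson[iu] < 0.05)

        g = nx.Graph()
        catalog = self.model.dataset
        for uid in est.uids:
            m_info = catalog.metabolite(uid)
            g.add_node(uid, fluid=m_info.fluid, platform=m_info.platform,
                       display_name=m_info.display_name)
        for i, j, k in zip(*iu, keep):
            if not k:
                continue
            g.add_edge(
                est.uids[i],
                est.uids[j],
                pcor=float(est.pcor[i, j]),
                pearson_r=float(self.R_plain[i, j]),
                p_pcor=float(p_pcor[i, j]) if p_pcor is not None else math.nan,
                p_pearson=float(p_pearson[i, j]),
                edge_type="pcor",
            )
        provenance = {
            "mode": mode,
            "cutoff": cutoff if mode == "cutoff" else None,
            "correction": correction if mode == "significance" else None,
            "require_pearson": require_pearson,
            "lambda_star": est.lambda_star,
            "kappa": self.null.kappa if self.null is not None else None,
            "n_eff": est.n_eff,
        }
        return GgmNetwork(g, provenance)


# ---------------------------------------------------------------------------
# networks


class GgmNetwork:
    """Undirected metabolite network with partial-correlation edge statistics."""

    def __init__(self, graph: nx.Graph, provenance: dict | None = None):
        for u, v in graph.edges():
            if u == v:
                raise DomainError("self-edges are not allowed")
        self.graph = graph
        self.provenance = provenance or {}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self, edge_type: str | None = None):
        for u, v, data in self.graph.edges(data=True):
            if edge_type is None or data.get("edge_type") == edge_type:
                yield u, v, data

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "uid_a": u,
                "uid_b": v,
                "pcor": data.get("pcor"),
                "pearson_r": data.get("pearson_r"),
                "p_pcor": data.get("p_pcor"),
                "p_pearson": data.get("p_pearson"),
                "edge_type": data.get("edge_type"),
            }
            for u, v, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=[
            "uid_a", "uid_b", "pcor", "pearson_r", "p_pcor", "p_pearson", "edge_type"
        ])


def merge_multifluid(net_a: GgmNetwork, net_b: GgmNetwork, match_on: str = "display_name") -> GgmNetwork:
    """Union of two fluid-specific networks plus same-metabolite cross edges.

    Cross edges link every pair of nodes from different input networks whose
    ``match_on`` key (display_name, kegg or hmdb; case-insensitive) agrees.
    """
    if match_on not in ("display_name", "kegg", "hmdb"):
        raise ConfigError(f"unknown match key {match_on!r}")
    overlap = set(net_a.graph.nodes) & set(net_b.graph.nodes)
    if overlap:
        raise DomainError(f"networks must cover disjoint uids; shared: {sorted(overlap)[:3]}")

    def key(graph, node):
        v = graph.nodes[node].get(match_on)
        return str(v).strip().lower() if v else None

    keys_a: dict[str, list[str]] = {}
    any_key = False
    for n in net_a.graph.nodes:
        k = key(net_a.graph, n)
        if k:
            any_key = True
            keys_a.setdefault(k, []).append(n)
    merged = nx.Graph()
    merged.add_nodes_from(net_a.graph.nodes(data=True))
    merged.add_nodes_from(net_b.graph.nodes(data=True))
    merged.add_edges_from(net_a.graph.edges(data=True))
    merged.add_edges_from(net_b.graph.edges(data=True))
    n_cross = 0
    for n in net_b.graph.nodes:
        k = key(net_b.graph, n)
        if k is None:
            continue
        any_key = True
        for partner in keys_a.get(k, []):
            merged.add_edge(partner, n, edge_type="same_metabolite")
            n_cross += 1
    if not any_key:
        raise ConfigError(f"match key {match_on!r} absent from all nodes")
    prov = {"merged_from": [net_a.provenance, net_b.provenance], "match_on": match_on,
            "n_same_metabolite_edges": n_cross}
    return GgmNetwork(merged, prov)


def annotate_and_export(
    net: GgmNetwork,
    stats_results,
    challenge: str,
    tp: int,
    path,
    fmt: str = "graphml",
) -> None:
    """Attach scan statistics as node attributes and write the network.

    Node size/colour semantics downstream: ``neg_log10_p`` and ``log2fc``
    from the (challenge, tp) rows of a paired scan; metabolites absent from
    the scan keep null attributes.  Formats: graphml, edge_tsv, json.
    """
    by_uid = {
        r.uid: r
        for r in stats_results
        if r.challenge == challenge.upper() and r.tp == tp and not r.is_null
    }
    for node in net.graph.nodes:
        r = by_uid.get(node)
        if r is not None:
            net.graph.nodes[node]["log2fc"] = float(r.log2fc)
            net.graph.nodes[node]["neg_log10_p"] = (
                -math.log10(r.p) if r.p > 0 else math.inf
            )
    if fmt == "graphml":
        g = net.graph.copy()
        for _, data in g.nodes(data=True):  # GraphML cannot carry None
            for k in [k for k, v in data.items() if v is None]:
                del data[k]
        for _, _, data in g.edges(data=True):
            for k in [k for k, v in data.items() if v is None or (
                isinstance(v, float) and math.isnan(v)
            )]:
                del data[k]
        nx.write_graphml(g, path)
    elif fmt == "edge_tsv":
        net.edge_frame().to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        payload = {
            "provenance": net.provenance,
            "nodes": [{"uid": n, **d} for n, d in net.graph.nodes(data=True)],
            "edges": [
                {"uid_a": u, "uid_b": v, **d} for u, v, d in net.graph.edges(data=True)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)
    else:
        raise ConfigError(f"unknown format {fmt!r}")
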