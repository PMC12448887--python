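"""Descriptive statistics for network layers.

Network-level structural characteristics (tie counts, composition, density,
reciprocity, transitivity, isolates), node-level centrality profiles
grouped by community role and by outcome, layer-overlap coefficients, tie
composition shares, ego-alter outcome cross-tabs, and summaries of the
perception items.

Betweenness, harmonic centrality and the global clustering coefficient are
delegated to networkx; the simple ratio statistics follow their standard
definitions directly. Harmonic centrality on directed layers uses
outgoing-path distances (how quickly information starting at a node can
reach the rest of the network).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data import LayerNetwork, PersonRecord, TieRecord


@dataclass(frozen=True)
class NetworkSummary:
    """One column of a structural-characteristics table."""

    layer: str
    directed: bool
    n_nodes: int
    n_ties: int
    pct_kin_ties: float | None
    pct_same_gender_ties: float | None
    mean_out_degree: float
    range_out_degree: tuple[int, int]
    mean_in_degree: float
    range_in_degree: tuple[int, int]
    density: float
    reciprocity: float
    transitivity: float
    n_isolates: int

    def as_series(self) -> pd.Series:
        d = self.__dict__.copy()
        d["range_out_degree"] = "{}-{}".format(*self.range_out_degree)
        d["range_in_degree"] = "{}-{}".format(*self.range_in_degree)
        return pd.Series(d, name=self.layer)


def density(net: LayerNetwork) -> float:
    """Ratio of realized ties to possible ties."""
    n = net.n
    if n < 2:
        raise ValueError("density undefined for networks with fewer than 2 nodes")
    possible = n * (n - 1) if net.directed else n * (n - 1) / 2
    return net.n_ties / possible


def reciprocity(net: LayerNetwork) -> float:
    """Proportion of arcs whose reverse arc also exists.

    An undirected layer encoded as mutual arcs has reciprocity 1 by
    construction.
    """
    if net.n_ties == 0:
        raise ValueError("reciprocity undefined for an empty tie set")
    if not net.directed:
        return 1.0
    arcset = set(net.arcs)
    mutual = sum((j, i) in arcset for (i, j) in net.arcs)
    return mutual / len(net.arcs)


def transitivity(net: LayerNetwork) -> float:
    """Global clustering coefficient (closed triplets / connected triplets)
    on the undirected projection."""
    g = net.to_networkx()
    gu = g.to_undirected() if net.directed else g
    triplets = sum(d * (d - 1) / 2 for _, d in gu.degree())
    if triplets == 0:
        raise ValueError("transitivity undefined: no connected triples")
    return nx.transitivity(gu)


def isolates(net: LayerNetwork) -> int:
    """Number of nodes with no tie in the layer (in either direction)."""
    return int(np.sum(net.total_degrees() == 0))


def degree_stats(net: LayerNetwork) -> dict:
    """Mean and range of in- and out-degree over all nodes incl. isolates.
    For an undirected layer in- and out-degree coincide with degree."""
    dout = net.out_degrees()
    din = net.in_degrees()
    return {
        "mean_out_degree": float(dout.mean()),
        "range_out_degree": (int(dout.min()), int(dout.max())),
        "mean_in_degree": float(din.mean()),
        "range_in_degree": (int(din.min()), int(din.max())),
    }


def jaccard_overlap(net_a: LayerNetwork, net_b: LayerNetwork) -> float:
    """Jaccard coefficient of the two tie sets (1 = identical, 0 = disjoint).

    When either layer is undirected both are compared as unordered pairs.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("layers must share a common node universe")
    as_pairs = not (net_a.directed and net_b.directed)

    def edge_set(net: LayerNetwork) -> set:
        if as_pairs:
            return {(min(i, j), max(i, j)) for i, j in net.arcs}
        return set(net.arcs)

    ea, eb = edge_set(net_a), edge_set(net_b)
    union = ea | eb
    if not union:
        raise ValueError("jaccard overlap undefined: both edge sets empty")
    return len(ea & eb) / len(union)


def network_summary(net: LayerNetwork) -> NetworkSummary:
    """Structural characteristics of one layer (a Table-1-style column)."""
    kin_flags = [m.get("kin") for m in net.meta]
    kin_known = [k for k in kin_flags if k is not None]
    pct_kin = 100.0 * sum(kin_known) / len(kin_known) if kin_known else None
    gender_pairs = [
        (m.get("ego_gender"), m.get("alter_gender"))
        for m in net.meta
        if m.get("ego_gender") and m.get("alter_gender")
    ]
    pct_same = (100.0 * sum(e == a for e, a in gender_pairs) / len(gender_pairs)
                if gender_pairs else None)
    ds = degree_stats(net)
    try:
        recip = reciprocity(net)
    except ValueError:
        recip = float("nan")
    try:
        trans = transitivity(net)
    except ValueError:
        trans = float("nan")
    return NetworkSummary(
        layer=net.name,
        directed=net.directed,
        n_nodes=net.n,
        n_ties=net.n_ties,
        pct_kin_ties=pct_kin,
        pct_same_gender_ties=pct_same,
        density=density(net),
        reciprocity=recip,
        transitivity=trans,
        n_isolates=isolates(net),
        **ds,
    )


def summary_table(nets: Sequence[LayerNetwork]) -> pd.DataFrame:
    """Structural characteristics with one column per layer."""
    return pd.DataFrame({net.name: network_summary(net).as_series() for net in nets})


# ---------------------------------------------------------------------------
# Centrality
# ---------------------------------------------------------------------------

def centrality_profile(net: LayerNetwork,
                       records: Sequence[PersonRecord] | None = None,
                       ) -> pd.DataFrame:
    """Per-node centrality table: in/out-degree, unnormalized vertex
    betweenness, harmonic centrality (outgoing-path distances, 1/inf = 0).

    When ``records`` is given, community role and outcome columns are
    attached for groupwise summaries.
    """
    g = net.to_networkx()
    betw = nx.betweenness_centrality(g, normalized=False)
    if net.directed:
        # networkx sums 1/d(v, u) over incoming paths; reverse for outgoing
        harm = nx.harmonic_centrality(g.reverse())
    else:
        harm = nx.harmonic_centrality(g)
    df = pd.DataFrame({
        "person_id": net.nodes,
        "in_degree": net.in_degrees(),
        "out_degree": net.out_degrees(),
        "betweenness": [betw[v] for v in net.nodes],
        "harmonic": [harm[v] for v in net.nodes],
    }).set_index("person_id")
    if records is not None:
        by_id = {r.person_id: r for r in records}
        df["community_role"] = [by_id[v].community_role for v in net.nodes]
        df["ipvaw_accept"] = [by_id[v].ipvaw_accept for v in net.nodes]
    return df


def centrality_by_group(profile: pd.DataFrame, group: str) -> pd.DataFrame:
    """Median and range of each centrality measure per group level."""
    measures = ["in_degree", "out_degree", "betweenness", "harmonic"]
    rows = {}
    for level, sub in profile.groupby(group, dropna=True):
        row = {}
        for m in measures:
            row[f"{m}_median"] = float(sub[m].median())
            row[f"{m}_min"] = float(sub[m].min())
            row[f"{m}_max"] = float(sub[m].max())
        row["n"] = len(sub)
        rows[level] = row
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Composition, cross-tabs, perceptions
# ---------------------------------------------------------------------------

def composition_summary(ties: Sequence[TieRecord],
                        records: Sequence[PersonRecord],
                        ) -> pd.DataFrame:
    """Shares of matched ties by kin status and gender pairing, overall and
    stratified by ego gender and by ego outcome (percentages)."""
    by_id = {r.person_id: r for r in records}
    rows = []
    for t in ties:
        if not t.matched:
            continue
        ego = by_id.get(t.ego_id)
        rows.append({
            "layer": t.layer,
            "kin": t.kin,
            "same_gender": (None if t.ego_gender is None or t.alter_gender is None
                            else int(t.ego_gender == t.alter_gender)),
            "ego_gender": t.ego_gender,
            "ego_accept": ego.ipvaw_accept if ego else None,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no matched ties to summarize")

    def shares(sub: pd.DataFrame) -> dict:
        out = {"n_ties": len(sub)}
        kin = sub["kin"].dropna()
        out["pct_kin"] = 100.0 * kin.mean() if len(kin) else float("nan")
        sg = sub["same_gender"].dropna()
        out["pct_same_gender"] = 100.0 * sg.mean() if len(sg) else float("nan")
        return out

    blocks = {("all", "all"): shares(df)}
    for g, sub in df.groupby("ego_gender", dropna=True):
        blocks[("ego_gender", g)] = shares(sub)
    for a, sub in df.groupby("ego_accept", dropna=True):
        blocks[("ego_accept", a)] = shares(sub)
    out = pd.DataFrame(blocks).T
    out.index.names = ["stratum", "level"]
    return out


def ego_alter_crosstab(net: LayerNetwork, outcome: Mapping[str, int],
                       gender_pairing: str | None = None) -> pd.DataFrame:
    """2x2 tie counts by (ego outcome x alter outcome).

    Directed layers count ordered ties; the household layer counts each
    unordered pair once (ego = the lexicographically first member, which is
    arbitrary but fixed). ``gender_pairing`` optionally restricts to
    ``"same"`` or ``"mixed"`` gender ties. The cell sum equals the number of
    ties counted.
    """
    counts = np.zeros((2, 2), dtype=int)
    for e, a, m in net.iter_ties():
        if gender_pairing is not None:
            eg, ag = m.get("ego_gender"), m.get("alter_gender")
            if eg is None or ag is None:
                continue
            same = eg == ag
            if (gender_pairing == "same") != same:
                continue
        ye, ya = outcome.get(e), outcome.get(a)
        if ye is None or ya is None:
            continue
        counts[int(ye), int(ya)] += 1
    return pd.DataFrame(counts,
                        index=pd.Index([0, 1], name="ego_accept"),
                        columns=pd.Index([0, 1], name="alter_accept"))


def perception_summary(records: Sequence[PersonRecord]) -> pd.DataFrame:
    """Distribution of perceived village-level acceptance by target gender.

    Rows: share of respondents reporting perceived acceptance > 0%, > 10%,
    > 50% among men and among women, overall and split by the respondent's
    own reported acceptance. Percentages over respondents answering the item.
    """
    df = pd.DataFrame({
        "men": [r.perceived_pct_men for r in records],
        "women": [r.perceived_pct_women for r in records],
        "own_accept": [r.ipvaw_accept for r in records],
    })

    def block(sub: pd.DataFrame) -> dict:
        out = {}
        for target in ("men", "women"):
            vals = sub[target].dropna()
            n = len(vals)
            out[f"n_{target}"] = n
            for thr in (0, 10, 50):
                out[f"pct_{target}_gt{thr}"] = (
                    100.0 * (vals > thr).mean() if n else float("nan"))
        return out

    blocks = {"all": block(df)}
    for a, sub in df.groupby("own_accept", dropna=True):
        blocks[f"own_accept={int(a)}"] = block(sub)
    return pd.DataFrame(blocks).T


def acceptance_prevalence(records: Sequence[PersonRecord]) -> pd.Series:
    """Percent reporting acceptance, overall and by gender."""
    df = pd.DataFrame({
        "accept": [r.ipvaw_accept for r in records],
        "gender": [r.gender for r in records],
    }).dropna(subset=["accept"])
    out = {"overall": 100.0 * df["accept"].mean()}
    for g, sub in df.groupby("gender"):
        out[g] = 100.0 * sub["accept"].mean()
    return pd.Series(out, name="pct_accepting")
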