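"""Data model and I/O for multilayer sociocentric network studies.

This module holds the census-level data model (one :class:`PersonRecord` per
surveyed individual), directed tie records elicited by name-generator
questions ("Who do you spend time chatting with?", "Who do you respect and
admire?"), the undirected household co-residency layer derived from shared
household identifiers, and the record-linkage step that matches free-text
alter names against the census using edit-distance similarity.

Conventions
-----------
* Identifiers are opaque strings; leading zeros are preserved. The study
  population uses a 4-digit household + 2-digit individual convention but
  nothing here requires it.
* Chatting and respect layers are directed; the household layer is
  undirected and stored as unordered pairs (expanded to mutual arcs only
  inside statistics that need a directed encoding).
* Ties whose alter could not be matched to a surveyed census record are kept
  in tie lists with ``matched=0`` but excluded from analysis networks.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
import scipy.sparse as sp

GENDERS = ("woman", "man")
EDUCATION_LEVELS = (
    "none",
    "some primary",
    "completed primary",
    "some secondary or beyond",
)
COMMUNITY_ROLES = (
    "none",
    "kebele leader",
    "religious leader",
    "militia",
    "teacher",
    "traditional birth attendant",
    "other",
)
LAYERS = ("chatting", "respect", "household")
DIRECTED_LAYERS = ("chatting", "respect")

NODE_TABLE_COLUMNS = (
    "person_id",
    "household_id",
    "village",
    "gender",
    "age",
    "education",
    "wealth_rank",
    "community_role",
    "ipvaw_accept",
    "is_reporter",
)
OPTIONAL_NODE_COLUMNS = ("perceived_pct_men", "perceived_pct_women")

EDGE_LIST_COLUMNS = ("ego_id", "alter_id")


@dataclass(frozen=True)
class PersonRecord:
    """One censused individual.

    ``ipvaw_accept`` is the binary outcome: 1 if the respondent agreed that
    it is sometimes acceptable for a husband to beat his wife, 0 otherwise.
    ``perceived_pct_men``/``perceived_pct_women`` are the respondent's
    estimate (0-100 in steps of 10) of how many men/women in their village
    accept it. ``is_reporter`` marks the ~50% subsample asked the network
    name generators.
    """

    person_id: str
    household_id: str
    village: str
    gender: str
    age: float
    education: str
    wealth_rank: int
    community_role: str
    ipvaw_accept: int | None
    is_reporter: int
    perceived_pct_men: int | None = None
    perceived_pct_women: int | None = None


def validate_person(rec: PersonRecord) -> list[str]:
    """Return a list of invariant violations (empty when the record is valid)."""
    errors: list[str] = []
    if rec.gender not in GENDERS:
        errors.append(f"unknown gender {rec.gender!r}")
    if rec.education not in EDUCATION_LEVELS:
        errors.append(f"unknown education level {rec.education!r}")
    if rec.community_role not in COMMUNITY_ROLES:
        errors.append(f"unknown community role {rec.community_role!r}")
    if rec.ipvaw_accept is not None and rec.ipvaw_accept not in (0, 1):
        errors.append(f"ipvaw_accept must be 0/1, got {rec.ipvaw_accept!r}")
    if not 1 <= rec.wealth_rank <= 10:
        errors.append(f"wealth_rank must be in 1..10, got {rec.wealth_rank!r}")
    if rec.is_reporter not in (0, 1):
        errors.append(f"is_reporter must be 0/1, got {rec.is_reporter!r}")
    for name in ("perceived_pct_men", "perceived_pct_women"):
        v = getattr(rec, name)
        if v is not None and (not 0 <= v <= 100 or v % 10 != 0):
            errors.append(f"{name} must be a multiple of 10 in 0..100, got {v!r}")
    if not 10 <= rec.age <= 120:
        errors.append(f"implausible age {rec.age!r}")
    return errors


@dataclass(frozen=True)
class TieRecord:
    """A single nomination (directed layers) or co-residency pair (household).

    ``kin`` is only meaningful on the chatting/respect layers; household ties
    carry ``kin=None`` (co-residents can be assumed to be near-universally
    related, so the flag is not stored).
    """

    ego_id: str
    alter_id: str
    layer: str
    kin: int | None = None
    ego_gender: str | None = None
    alter_gender: str | None = None
    matched: int = 1


@dataclass(frozen=True)
class AlterNameRecord:
    """Free-text alter description from a name generator.

    Three names follow the local convention: given name, father's name,
    paternal grandfather's name.
    """

    given_name: str
    father_name: str = ""
    grandfather_name: str = ""
    gender: str | None = None
    age: float | None = None
    relationship: str | None = None
    same_village: bool | None = None


@dataclass(frozen=True)
class CensusNameEntry:
    """Census-side name fields used for alter matching."""

    person_id: str
    given_name: str
    father_name: str = ""
    grandfather_name: str = ""
    gender: str | None = None


@dataclass
class ReadReport:
    """Row-level validation outcome of a file read: nothing is dropped silently."""

    n_rows: int = 0
    n_ok: int = 0
    errors: list[str] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return self.n_rows - self.n_ok


class LayerNetwork:
    """A single network layer over a fixed node universe.

    Arcs are stored as integer index pairs into ``nodes``. For undirected
    layers each unordered pair is stored once as ``(min, max)``. Per-arc
    metadata (kin flag, gender pairing) is carried in ``meta``, aligned with
    ``arcs``.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        arcs: Iterable[tuple[str, str]],
        directed: bool,
        name: str = "",
        meta: Sequence[Mapping] | None = None,
    ):
        self.nodes: tuple[str, ...] = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids")
        self.directed = bool(directed)
        self.name = name
        self._index = {v: i for i, v in enumerate(self.nodes)}
        arc_idx: list[tuple[int, int]] = []
        meta_list: list[dict] = []
        seen: set[tuple[int, int]] = set()
        meta = list(meta) if meta is not None else None
        for k, (ego, alter) in enumerate(arcs):
            i, j = self._index[ego], self._index[alter]
            if i == j:
                raise ValueError(f"self-loop at node {ego!r}")
            key = (i, j) if self.directed else (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            arc_idx.append(key)
            meta_list.append(dict(meta[k]) if meta is not None else {})
        self.arcs: list[tuple[int, int]] = arc_idx
        self.meta: list[dict] = meta_list

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_ties(self) -> int:
        return len(self.arcs)

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def iter_ties(self) -> Iterator[tuple[str, str, dict]]:
        for (i, j), m in zip(self.arcs, self.meta):
            yield self.nodes[i], self.nodes[j], m

    def adjacency(self) -> sp.csr_matrix:
        """Binary adjacency. Directed layers: A[i, j] = 1 iff arc i->j.
        Undirected layers: symmetric."""
        n = self.n
        if not self.arcs:
            return sp.csr_matrix((n, n), dtype=np.int64)
        rows, cols = zip(*self.arcs)
        data = np.ones(len(rows), dtype=np.int64)
        a = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
        if not self.directed:
            a = a + a.T
        a.data[:] = 1
        return a

    def out_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def in_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=0)).ravel()

    def total_degrees(self) -> np.ndarray:
        a = self.adjacency()
        if self.directed:
            return np.asarray(a.sum(axis=1)).ravel() + np.asarray(a.sum(axis=0)).ravel()
        return np.asarray(a.sum(axis=1)).ravel()

    # -- transforms --------------------------------------------------------

    def transpose(self) -> "LayerNetwork":
        """Reverse every arc (incoming-tie encoding); undirected layers are
        returned as an identical copy."""
        if not self.directed:
            return self.subset(lambda e, a, m: True)
        net = LayerNetwork.__new__(LayerNetwork)
        net.nodes = self.nodes
        net.directed = True
        net.name = self.name + "_transposed" if self.name else "transposed"
        net._index = self._index
        net.arcs = [(j, i) for (i, j) in self.arcs]
        net.meta = [dict(m) for m in self.meta]
        return net

    def subset(self, keep: Callable[[str, str, dict], bool], name: str | None = None) -> "LayerNetwork":
        """New network on the same node universe keeping ties for which
        ``keep(ego_id, alter_id, meta)`` is true."""
        kept = [(e, a, m) for e, a, m in self.iter_ties() if keep(e, a, m)]
        return LayerNetwork(
            self.nodes,
            [(e, a) for e, a, _ in kept],
            directed=self.directed,
            name=self.name if name is None else name,
            meta=[m for _, _, m in kept],
        )

    def restrict_nodes(self, node_ids: Iterable[str], name: str | None = None) -> "LayerNetwork":
        """Induced subnetwork on the given node subset."""
        keep = set(node_ids)
        ties = [(e, a, m) for e, a, m in self.iter_ties() if e in keep and a in keep]
        return LayerNetwork(
            [v for v in self.nodes if v in keep],
            [(e, a) for e, a, _ in ties],
            directed=self.directed,
            name=self.name if name is None else name,
            meta=[m for _, _, m in ties],
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        for e, a, m in self.iter_ties():
            g.add_edge(e, a, **m)
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        g = self.to_networkx()
        for _, _, d in g.edges(data=True):
            for k in list(d):
                if d[k] is None:
                    del d[k]
        nx.write_graphml(g, path)

    def to_edgelist_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["ego_id", "alter_id", "kin", "ego_gender", "alter_gender", "layer"])
            for e, a, m in self.iter_ties():
                w.writerow([e, a, m.get("kin", ""), m.get("ego_gender", ""),
                            m.get("alter_gender", ""), self.name])

    def __eq__(self, other) -> bool:
        if not isinstance(other, LayerNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.directed == other.directed
            and sorted(self.arcs) == sorted(other.arcs)
        )

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return f"<LayerNetwork {self.name or '?'}: {self.n} nodes, {self.n_ties} {kind} ties>"


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

def _parse_optional_pct(raw: str) -> int | None:
    if raw is None or str(raw).strip() == "":
        return None
    return int(float(raw))


def read_node_table(path) -> tuple[list[PersonRecord], ReadReport]:
    """Read the node attribute table (CSV, UTF-8, header mandatory).

    Rows that fail validation are recorded in the report and skipped; a
    missing required column raises immediately.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in NODE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"node table missing required columns: {missing}")
    report = ReadReport(n_rows=len(df))
    records: list[PersonRecord] = []
    seen_ids: set[str] = set()
    for pos, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            rec = PersonRecord(
                person_id=rowd["person_id"].strip(),
                household_id=rowd["household_id"].strip(),
                village=rowd["village"].strip(),
                gender=rowd["gender"].strip(),
                age=float(rowd["age"]),
                education=rowd["education"].strip(),
                wealth_rank=int(float(rowd["wealth_rank"])),
                community_role=rowd["community_role"].strip(),
                ipvaw_accept=(int(float(rowd["ipvaw_accept"]))
                              if str(rowd["ipvaw_accept"]).strip() != "" else None),
                is_reporter=int(float(rowd["is_reporter"])),
                perceived_pct_men=_parse_optional_pct(rowd.get("perceived_pct_men", "")),
                perceived_pct_women=_parse_optional_pct(rowd.get("perceived_pct_women", "")),
            )
        except (ValueError, TypeError) as exc:
            report.errors.append(f"row {pos}: unparseable ({exc})")
            continue
        problems = validate_person(rec)
        if rec.person_id in seen_ids:
            problems.append(f"duplicate person_id {rec.person_id!r}")
        if problems:
            report.errors.append(f"row {pos}: " + "; ".join(problems))
            continue
        seen_ids.add(rec.person_id)
        records.append(rec)
        report.n_ok += 1
    return records, report


def read_edge_list(path, layer: str,
                   records: Sequence[PersonRecord] | None = None,
                   ) -> tuple[list[TieRecord], ReadReport]:
    """Read one layer's edge list CSV (columns ego_id, alter_id [, kin,
    alter_gender, layer]).

    Self-loops are rejected into the report. When ``records`` is given, ties
    whose alter is absent from the census are flagged ``matched=0`` (they are
    kept in the returned list but excluded from analysis networks), and ego
    genders are filled from the census.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_LIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge list missing required columns: {missing}")
    by_id = {r.person_id: r for r in records} if records is not None else None
    report = ReadReport(n_rows=len(df))
    ties: list[TieRecord] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        ego = rowd["ego_id"].strip()
        alter = rowd["alter_id"].strip()
        if ego == alter:
            report.errors.append(f"row {pos}: self-loop {ego!r} rejected")
            continue
        kin_raw = str(rowd.get("kin", "")).strip()
        kin = int(float(kin_raw)) if kin_raw != "" and layer != "household" else None
        ego_gender = rowd.get("ego_gender", "").strip() or None
        alter_gender = rowd.get("alter_gender", "").strip() or None
        matched = 1
        if by_id is not None:
            if ego not in by_id:
                report.errors.append(f"row {pos}: unknown ego {ego!r}")
                continue
            ego_gender = by_id[ego].gender
            if alter in by_id:
                alter_gender = by_id[alter].gender
            else:
                matched = 0
        ties.append(TieRecord(ego_id=ego, alter_id=alter, layer=layer, kin=kin,
                              ego_gender=ego_gender, alter_gender=alter_gender,
                              matched=matched))
        report.n_ok += 1
    return ties, report


def build_layer(ties: Sequence[TieRecord], records: Sequence[PersonRecord],
                layer: str) -> LayerNetwork:
    """Analysis network for one layer: matched ties only, full census node set."""
    node_ids = [r.person_id for r in records]
    kept = [t for t in ties if t.layer == layer and t.matched]
    return LayerNetwork(
        node_ids,
        [(t.ego_id, t.alter_id) for t in kept],
        directed=layer in DIRECTED_LAYERS,
        name=layer,
        meta=[{"kin": t.kin, "ego_gender": t.ego_gender, "alter_gender": t.alter_gender}
              for t in kept],
    )


# ---------------------------------------------------------------------------
# Household layer
# ---------------------------------------------------------------------------

def household_ties(records: Sequence[PersonRecord],
                   head_map: Mapping[str, Sequence[str]] | None = None,
                   ) -> list[TieRecord]:
    """Unordered co-residency ties (each pair once).

    Within each household every pair of members is tied (a clique). A person
    heading several households (``head_map: person_id -> household_ids``) is
    additionally tied to all members of each household they head, but
    non-head members of different households are *not* tied to each other.
    """
    by_household: dict[str, list[PersonRecord]] = defaultdict(list)
    by_id = {r.person_id: r for r in records}
    for r in records:
        by_household[r.household_id].append(r)
    pairs: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        if a != b:
            pairs.add((min(a, b), max(a, b)))

    for members in by_household.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                add(members[i].person_id, members[j].person_id)
    if head_map:
        for head, households in head_map.items():
            if head not in by_id:
                raise KeyError(f"head {head!r} not in census")
            for hh in households:
                for member in by_household.get(hh, []):
                    add(head, member.person_id)
    ties = []
    for a, b in sorted(pairs):
        ties.append(TieRecord(
            ego_id=a, alter_id=b, layer="household", kin=None,
            ego_gender=by_id[a].gender, alter_gender=by_id[b].gender,
        ))
    return ties


def build_household_network(records: Sequence[PersonRecord],
                            head_map: Mapping[str, Sequence[str]] | None = None,
                            ) -> LayerNetwork:
    """Undirected household co-residency layer over the full census.

    Single-member households become isolates (no error).
    """
    ties = household_ties(records, head_map)
    return LayerNetwork(
        [r.person_id for r in records],
        [(t.ego_id, t.alter_id) for t in ties],
        directed=False,
        name="household",
        meta=[{"kin": None, "ego_gender": t.ego_gender, "alter_gender": t.alter_gender}
              for t in ties],
    )


# ---------------------------------------------------------------------------
# Alter-name record linkage
# ---------------------------------------------------------------------------

def levenshtein_similarity(a: str, b: str) -> float:
    """Normalized edit-distance similarity: 1 - d(a, b) / max(|a|, |b|).

    Case-insensitive; two empty strings are defined as similarity 1.
    """
    a = a.strip().casefold()
    b = b.strip().casefold()
    if not a and not b:
        return 1.0
    d = edlib.align(a, b)["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def name_similarity(alter: AlterNameRecord, census: CensusNameEntry) -> tuple[float, float]:
    """(combined, given-name) similarity between an alter record and a census
    entry: the mean of per-field normalized similarities over the name fields
    present on the alter side."""
    fields = [("given_name", alter.given_name, census.given_name)]
    if alter.father_name.strip():
        fields.append(("father_name", alter.father_name, census.father_name))
    if alter.grandfather_name.strip():
        fields.append(("grandfather_name", alter.grandfather_name, census.grandfather_name))
    sims = {name: levenshtein_similarity(x, y) for name, x, y in fields}
    return sum(sims.values()) / len(sims), sims["given_name"]


@dataclass(frozen=True)
class MatchResult:
    alter: AlterNameRecord
    person_id: str | None
    similarity: float


@dataclass
class MatchReport:
    results: list[MatchResult]

    @property
    def match_rate(self) -> float:
        if not self.results:
            return float("nan")
        return sum(r.person_id is not None for r in self.results) / len(self.results)

    def as_mapping(self) -> dict[int, str | None]:
        return {i: r.person_id for i, r in enumerate(self.results)}


def match_alters(alters: Sequence[AlterNameRecord],
                 census: Sequence[CensusNameEntry],
                 threshold: float = 0.80) -> MatchReport:
    """Match free-text alter names against census entries.

    Each alter is mapped to the census entry maximizing the combined
    normalized edit-distance similarity over the three name fields, subject
    to a hard gender constraint (when both sides report a gender). Best
    matches below ``threshold`` are returned unmatched. Ties are broken by
    higher given-name similarity, then by smallest person_id, making the
    procedure deterministic.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    results: list[MatchResult] = []
    for alter in alters:
        if not alter.given_name.strip():
            raise ValueError("alter record must have a non-empty given name")
        best: tuple[float, float, str] | None = None  # (combined, given_sim, person_id)
        for entry in census:
            if alter.gender is not None and entry.gender is not None \
                    and alter.gender != entry.gender:
                continue
            combined, given_sim = name_similarity(alter, entry)
            cand = (combined, given_sim, entry.person_id)
            if best is None or (cand[0], cand[1], _neg_id(cand[2])) > \
                    (best[0], best[1], _neg_id(best[2])):
                best = cand
        if best is not None and best[0] >= threshold:
            results.append(MatchResult(alter, best[2], best[0]))
        else:
            results.append(MatchResult(alter, None, best[0] if best else 0.0))
    return MatchReport(results)


class _neg_id(str):
    """String wrapper whose ordering is reversed, so that tuple max() prefers
    the smallest person_id on otherwise equal similarity."""

    def __lt__(self, other):  # type: ignore[override]
        return str(self) > str(other)

    def __gt__(self, other):  # type: ignore[override]
        return str(self) < str(other)


# ---------------------------------------------------------------------------
# Convenience
# ---------------------------------------------------------------------------

def records_to_dataframe(records: Sequence[PersonRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    return df.set_index("person_id", drop=False)


def write_node_table(records: Sequence[PersonRecord], path) -> None:
    df = records_to_dataframe(records).reset_index(drop=True)
    df.to_csv(path, index=False)


def write_edge_list(ties: Sequence[TieRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["ego_id", "alter_id", "kin", "ego_gender", "alter_gender", "layer"])
        for t in ties:
            w.writerow([t.ego_id, t.alter_id,
                        "" if t.kin is None else t.kin,
                        t.ego_gender or "", t.alter_gender or "", t.layer])


def set_outcomes(records: Sequence[PersonRecord], outcomes: Mapping[str, int]
                 ) -> list[PersonRecord]:
    """Return records with ipvaw_accept replaced from a person_id -> 0/1 map."""
    return [replace(r, ipvaw_accept=int(outcomes[r.person_id])) for r in records]
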