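"""Readers and writers for the five flat inputs and the fact-matrix format.

All tabular inputs are UTF-8 TSV with a header line, matching the flat
exports one typically pulls from DrugBank / SIDER / HAPPI-style resources.
The ontology is a standard OBO 1.2 subset ([Term] stanzas with id, name,
namespace and is_a), read through :mod:`obonet`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd

from .errors import FormatError, StructuralError

logger = logging.getLogger(__name__)

#: ICD-10 code: letter + two digits, optional decimal sub-code, or a
#: category range such as "I30-I52".
_ICD10_SINGLE = re.compile(r"^[A-Z]\d{2}(\.\d+)?$")
_ICD10_RANGE = re.compile(r"^[A-Z]\d{2}-[A-Z]\d{2}$")


def canonical_adr_name(name: str) -> str:
    """Canonicalize an ADR label: trim, collapse whitespace, case-fold."""
    return " ".join(name.split()).casefold()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugTargetMap:
    """Binary drug-docks-protein relation (DrugBank-style extract)."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for drug, protein in self.pairs:
            if not drug or not protein:
                raise FormatError("empty drug_id or protein_id in drug-target pair")

    @property
    def drugs(self) -> set[str]:
        return {d for d, _ in self.pairs}

    @property
    def proteins(self) -> set[str]:
        return {p for _, p in self.pairs}


@dataclass(frozen=True)
class DrugADRMap:
    """Drug to adverse-reaction-name relation (SIDER-style extract).

    ADR names are stored canonicalized (trimmed, whitespace-collapsed,
    case-folded) so they join reliably against the ICD-10 map.
    """

    pairs: frozenset[tuple[str, str]]

    @property
    def drugs(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def adrs_of(self, drug_id: str) -> set[str]:
        return {a for d, a in self.pairs if d == drug_id}


@dataclass(frozen=True)
class ADRIcdMap:
    """ADR name -> ICD-10 code map (keys canonicalized)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for name, code in self.entries.items():
            if not (_ICD10_SINGLE.match(code) or _ICD10_RANGE.match(code)):
                raise FormatError(f"malformed ICD-10 code {code!r} for ADR {name!r}")

    def category(self, adr_name: str) -> str | None:
        """3-character ICD-10 category for an ADR name, or None if unmapped.

        Range codes (e.g. "I30-I52") resolve to the range's lower bound.
        """
        code = self.entries.get(canonical_adr_name(adr_name))
        if code is None:
            return None
        return code.split("-")[0].split(".")[0]


class PPINetwork:
    """Undirected protein graph with a 1-5 confidence star grade per edge."""

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise StructuralError(f"self-edge on {u!r}")
            stars = data.get("stars")
            if not isinstance(stars, int) or not 1 <= stars <= 5:
                raise FormatError(f"edge ({u},{v}) has invalid stars {stars!r}")

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str, int]]) -> "PPINetwork":
        g = nx.Graph()
        for u, v, stars in edges:
            g.add_edge(u, v, stars=stars)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> set[tuple[str, str, int]]:
        """Edge set with canonically ordered endpoints."""
        return {
            (min(u, v), max(u, v), d["stars"])
            for u, v, d in self.graph.edges(data=True)
        }

    def neighbors(self, node: str) -> list[str]:
        if node not in self.graph:
            return []
        return list(self.graph.neighbors(node))

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PPINetwork) and self.edges() == other.edges() \
            and self.nodes == other.nodes

    def __repr__(self) -> str:
        return (f"PPINetwork({self.graph.number_of_nodes()} proteins, "
                f"{self.graph.number_of_edges()} interactions)")


@dataclass
class GODag:
    """Biological-process ontology as a rooted DAG plus protein annotations.

    ``parents`` maps each term to its direct is_a parents; ``root`` is the
    single parentless term ("biological process", level 1).
    """

    terms: dict[str, str]                 # go_id -> name
    parents: dict[str, set[str]]          # go_id -> direct is_a parents
    root: str
    annotations: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [t for t in self.terms if not self.parents.get(t)]
        if len(roots) != 1 or roots[0] != self.root:
            raise StructuralError(
                f"ontology must have exactly one parentless term; found {roots}")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise StructuralError("is_a relation contains a cycle")
        for protein, gos in self.annotations.items():
            unknown = gos - self.terms.keys()
            if unknown:
                raise StructuralError(
                    f"annotations of {protein!r} reference unknown terms {unknown}")

    def ancestors(self, go_id: str) -> set[str]:
        """All is_a ancestors of a term (excluding the term itself)."""
        seen: set[str] = set()
        stack = list(self.parents.get(go_id, ()))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents.get(t, ()))
        return seen


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError:
        logger.warning("%s is empty; returning empty table", path)
        return pd.DataFrame(columns=columns)
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    # a short row leaves NaN in trailing columns
    bad = df[columns].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FormatError(f"{path}: malformed row at line {line}")
    return df


def read_drug_target_table(path: str | Path) -> DrugTargetMap:
    """Read a two-column drug_id/protein_id TSV into a deduplicated pair set."""
    df = _read_tsv(path, ["drug_id", "protein_id"])
    if df.empty:
        logger.warning("%s: no drug-target pairs", path)
    pairs = frozenset(zip(df["drug_id"], df["protein_id"]))
    return DrugTargetMap(pairs)


def read_drug_adr_table(path: str | Path) -> DrugADRMap:
    """Read a drug_id/adr_name TSV; ADR names are canonicalized."""
    df = _read_tsv(path, ["drug_id", "adr_name"])
    if df.empty:
        logger.warning("%s: no drug-ADR pairs", path)
    pairs = frozenset(
        (d, canonical_adr_name(a)) for d, a in zip(df["drug_id"], df["adr_name"]))
    return DrugADRMap(pairs)


def read_ppi_table(path: str | Path) -> PPINetwork:
    """Read protein_a/protein_b/stars TSV into an undirected star-graded graph.

    Self interactions are dropped (with a logged count); a repeated unordered
    pair keeps the maximum star grade.
    """
    df = _read_tsv(path, ["protein_a", "protein_b", "stars"])
    g = nx.Graph()
    self_edges = 0
    for a, b, stars_raw in zip(df["protein_a"], df["protein_b"], df["stars"]):
        try:
            stars = int(stars_raw)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-integer stars value {stars_raw!r}")
        if float(stars_raw) != stars:
            raise FormatError(f"{path}: non-integer stars value {stars_raw!r}")
        if not 1 <= stars <= 5:
            raise FormatError(f"{path}: stars {stars} outside 1..5")
        if a == b:
            self_edges += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["stars"] = max(g[a][b]["stars"], stars)
        else:
            g.add_edge(a, b, stars=stars)
    if self_edges:
        logger.info("%s: dropped %d self interaction(s)", path, self_edges)
    return PPINetwork(g)


def read_icd10_table(path: str | Path) -> ADRIcdMap:
    """Read an adr_name/icd10_code TSV into a validated name->code map."""
    df = _read_tsv(path, ["adr_name", "icd10_code"])
    entries = {
        canonical_adr_name(name): code
        for name, code in zip(df["adr_name"], df["icd10_code"])
    }
    return ADRIcdMap(entries)


def read_obo(obo_path: str | Path, annot_path: str | Path) -> GODag:
    """Read an OBO ontology plus a protein_id/go_id annotation TSV.

    Only biological_process terms are kept; is_a links restricted to kept
    terms form the parent relation, and the unique parentless kept term is
    the root. Annotations to unknown terms are dropped with a logged count.
    """
    graph = obonet.read_obo(str(obo_path))
    terms: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    for node, data in graph.nodes(data=True):
        if data.get("namespace") != "biological_process":
            continue
        terms[node] = data.get("name", node)
    for node in terms:
        # obonet encodes "child is_a parent" as edge child -> parent
        ps = {
            p for _, p, key in graph.out_edges(node, keys=True)
            if key == "is_a" and p in terms
        }
        parents[node] = ps
    roots = [t for t in terms if not parents.get(t)]
    if len(roots) != 1:
        raise StructuralError(
            f"expected a single biological_process root, found {len(roots)}: {sorted(roots)}")

    annot_df = _read_tsv(annot_path, ["protein_id", "go_id"])
    annotations: dict[str, set[str]] = {}
    dropped = 0
    for protein, go_id in zip(annot_df["protein_id"], annot_df["go_id"]):
        if go_id not in terms:
            dropped += 1
            continue
        annotations.setdefault(protein, set()).add(go_id)
    if dropped:
        logger.info("%s: dropped %d annotation(s) to unknown terms",
                    annot_path, dropped)
    return GODag(terms=terms, parents=parents, root=roots[0],
                 annotations=annotations)


def load_cardiotoxicity_icd10() -> ADRIcdMap:
    """The packaged cardiotoxicity ADR -> ICD-10 map (29 curated entries)."""
    ref = resources.files("adrnet").joinpath("data/cardiotoxicity_icd10.tsv")
    with resources.as_file(ref) as path:
        return read_icd10_table(path)


# ---------------------------------------------------------------------------
# Writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------

def write_drug_target_table(m: DrugTargetMap, path: str | Path) -> None:
    df = pd.DataFrame(sorted(m.pairs), columns=["drug_id", "protein_id"])
    df.to_csv(path, sep="\t", index=False)


def write_drug_adr_table(m: DrugADRMap, path: str | Path) -> None:
    df = pd.DataFrame(sorted(m.pairs), columns=["drug_id", "adr_name"])
    df.to_csv(path, sep="\t", index=False)


def write_ppi_table(net: PPINetwork, path: str | Path) -> None:
    rows = sorted(net.edges())
    df = pd.DataFrame(rows, columns=["protein_a", "protein_b", "stars"])
    df.to_csv(path, sep="\t", index=False)


def write_icd10_table(m: ADRIcdMap, path: str | Path) -> None:
    df = pd.DataFrame(sorted(m.entries.items()),
                      columns=["adr_name", "icd10_code"])
    df.to_csv(path, sep="\t", index=False)
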