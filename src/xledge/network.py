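"""Edgotype network assembly and topological classification of crosslinks.

Nodes are unique peptide species (sequence + modifications + crosslink
site, light/heavy collapsed); edges are crosslinks between two peptides.
Every edge is classified as intra-molecular (one protein molecule
suffices), inter-protein, unambiguous homodimer (overlapping peptides
whose sequence occurs once in the protein, forcing two subunits), or
ambiguous homooligomer. Intermolecular edges deduplicate into binary
protein interactions; nodal distance situates each interaction in a
known-PPI graph.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "LinkClass",
    "CrosslinkRecord",
    "BinaryInteraction",
    "classify_link",
    "binary_interactions",
    "peptide_redundancy",
    "nodal_distance",
    "EdgotypeNetwork",
]

INTERMOLECULAR = frozenset({"inter", "homooligomer_ambiguous", "homodimer_unambiguous"})


class LinkClass(str, enum.Enum):
    INTRA = "intra"
    INTER = "inter"
    HOMOOLIGOMER_AMBIGUOUS = "homooligomer_ambiguous"
    HOMODIMER_UNAMBIGUOUS = "homodimer_unambiguous"

    @property
    def intermolecular(self) -> bool:
        return self.value in INTERMOLECULAR


@dataclass(frozen=True)
class CrosslinkRecord:
    """One row of the crosslink-pair table (the inter-module schema).

    Sites and starts are 1-based; ``site_a``/``site_b`` index into the
    peptide, not the protein.
    """

    spectrum_id: str
    pep_a: str
    site_a: int
    protein_a: str
    start_a: int
    pep_b: str
    site_b: int
    protein_b: str
    start_b: int
    mods_a: str = ""
    mods_b: str = ""
    n_decoy: int = 0
    ppm_error: float = 0.0

    @property
    def end_a(self) -> int:
        return self.start_a + len(self.pep_a) - 1

    @property
    def end_b(self) -> int:
        return self.start_b + len(self.pep_b) - 1

    @property
    def pair_key(self) -> str:
        sa = self.start_a + self.site_a - 1
        sb = self.start_b + self.site_b - 1
        ends = sorted([(self.protein_a, sa), (self.protein_b, sb)])
        return f"{ends[0][0]}:{ends[0][1]}--{ends[1][0]}:{ends[1][1]}"


def _count_occurrences(needle: str, haystack: str) -> int:
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def classify_link(rec: CrosslinkRecord, protein_seqs: dict[str, str]) -> LinkClass:
    """Topological class of one crosslink.

    Different proteins -> inter. Same protein with disjoint peptide
    ranges -> intra (the conservative single-molecule reading).
    Overlapping ranges force two subunits: homodimer_unambiguous when
    both peptide sequences occur exactly once in the protein, else
    homooligomer_ambiguous.
    """
    if rec.protein_a != rec.protein_b:
        return LinkClass.INTER
    try:
        seq = protein_seqs[rec.protein_a]
    except KeyError:
        raise ValueError(f"protein {rec.protein_a!r} not in sequence database") from None
    overlap = rec.start_a <= rec.end_b and rec.start_b <= rec.end_a
    if not overlap:
        return LinkClass.INTRA
    if _count_occurrences(rec.pep_a, seq) == 1 and _count_occurrences(rec.pep_b, seq) == 1:
        return LinkClass.HOMODIMER_UNAMBIGUOUS
    return LinkClass.HOMOOLIGOMER_AMBIGUOUS


@dataclass(frozen=True)
class BinaryInteraction:
    protein_pair: tuple[str, str]
    kind: str  # "inter" | "homooligomer"
    supporting_edge_count: int


def binary_interactions(
    edges: list[tuple[CrosslinkRecord, LinkClass]],
) -> list[BinaryInteraction]:
    """Deduplicate intermolecular edges into unique binary interactions.

    Homodimer/homooligomer links collapse to the (P, P) self pair.
    """
    support: dict[tuple[str, str], int] = {}
    for rec, cls in edges:
        if not cls.intermolecular:
            continue
        pair = tuple(sorted((rec.protein_a, rec.protein_b)))
        support[pair] = support.get(pair, 0) + 1
    out = []
    for pair in sorted(support):
        kind = "homooligomer" if pair[0] == pair[1] else "inter"
        out.append(BinaryInteraction(pair, kind, support[pair]))
    return out


REDUNDANCY_BINS = ("1", "2", "3-5", ">5_or_short")


def peptide_redundancy(peptides: list[str], database: dict[str, str]) -> dict[str, int]:
    """Histogram of peptide-to-protein mapping redundancy.

    Each peptide is counted by the number of database proteins containing
    it as a substring; peptides shorter than 5 residues land in the final
    bin regardless of hit count.
    """
    if not database:
        raise ValueError("database must be non-empty")
    hist = dict.fromkeys(REDUNDANCY_BINS, 0)
    seqs = list(database.values())
    for pep in peptides:
        hits = sum(1 for s in seqs if pep in s)
        if len(pep) < 5 or hits > 5:
            hist[">5_or_short"] += 1
        elif hits >= 3:
            hist["3-5"] += 1
        elif hits == 2:
            hist["2"] += 1
        else:
            hist["1"] += 1
    return hist


def nodal_distance(
    interactions: list[tuple[str, str]], known_ppi: list[tuple[str, str]]
) -> dict[tuple[str, str], int | None]:
    """Distance of each interaction from the known-PPI graph.

    0 when the pair is a known edge; otherwise shortest-path length
    between the two proteins minus one (1 = one shared partner); None
    when either protein is absent or unreachable.
    """
    g = nx.Graph()
    g.add_edges_from(known_ppi)
    out: dict[tuple[str, str], int | None] = {}
    for a, b in interactions:
        key = (a, b)
        if g.has_edge(a, b):
            out[key] = 0
        elif a in g and b in g:
            try:
                out[key] = nx.shortest_path_length(g, a, b) - 1
            except nx.NetworkXNoPath:
                out[key] = None
        else:
            out[key] = None
    return out


def _node_key(pep: str, mods: str, site: int) -> str:
    return f"{pep}|{mods}|{site}"


@dataclass
class EdgotypeNetwork:
    """Peptide-node / crosslink-edge network with quantitative annotation.

    Backed by a networkx MultiGraph: node keys collapse the light/heavy
    label state; parallel edges between the same node pair are kept
    distinct by their site pair. Self loops are permitted only for
    unambiguous homodimers.
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)

    @classmethod
    def build(
        cls,
        records: list[CrosslinkRecord],
        classes: dict[str, LinkClass] | None = None,
        quant: dict[str, "object"] | None = None,
        protein_log2: dict[str, float] | None = None,
        color_threshold: float = 1.0,
    ) -> "EdgotypeNetwork":
        """Assemble the network from classified, quantified crosslink rows.

        ``classes`` and ``quant`` are keyed by ``CrosslinkRecord.pair_key``;
        ``protein_log2`` carries protein-level SILAC means for node colour
        classes (up/down/unchanged/unquantified at ``|log2| > threshold``).
        """
        net = cls()
        g = net.graph
        for rec in records:
            cls_ = classes.get(rec.pair_key) if classes else None
            if cls_ is not None and not isinstance(cls_, LinkClass):
                cls_ = LinkClass(cls_)
            for pep, mods, site, prot in (
                (rec.pep_a, rec.mods_a, rec.site_a, rec.protein_a),
                (rec.pep_b, rec.mods_b, rec.site_b, rec.protein_b),
            ):
                node = _node_key(pep, mods, site)
                if node not in g:
                    plog = (protein_log2 or {}).get(prot)
                    if plog is None:
                        color = "unquantified"
                    elif plog > color_threshold:
                        color = "up"
                    elif plog < -color_threshold:
                        color = "down"
                    else:
                        color = "unchanged"
                    g.add_node(
                        node,
                        peptide=pep,
                        mods=mods,
                        site=int(site),
                        protein=prot,
                        protein_log2=float(plog) if plog is not None else float("nan"),
                        color_class=color,
                    )
            na = _node_key(rec.pep_a, rec.mods_a, rec.site_a)
            nb = _node_key(rec.pep_b, rec.mods_b, rec.site_b)
            if na == nb and cls_ is not None and cls_ is not LinkClass.HOMODIMER_UNAMBIGUOUS:
                raise ValueError(f"self-loop edge {rec.pair_key} is not an unambiguous homodimer")
            qs = (quant or {}).get(rec.pair_key)
            attrs = {
                "pair_key": rec.pair_key,
                "site_a": int(rec.site_a),
                "site_b": int(rec.site_b),
                "link_class": cls_.value if cls_ is not None else "",
                "mean_log2_rs": float(getattr(qs, "mean_log2_rs", float("nan"))),
                "ci_width": float(getattr(qs, "ci_width", float("nan"))),
                "significant": bool(getattr(qs, "significant", False)),
            }
            g.add_edge(na, nb, key=f"{rec.site_a}-{rec.site_b}", **attrs)
        return net

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def proteins(self) -> set[str]:
        return {d["protein"] for _, d in self.graph.nodes(data=True)}

    def to_graphml(self, path: str) -> None:
        nx.write_graphml(self.graph, path)

    @classmethod
    def from_graphml(cls, path: str) -> "EdgotypeNetwork":
        g = nx.read_graphml(path, force_multigraph=True)
        return cls(graph=nx.MultiGraph(g))
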