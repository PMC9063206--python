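"""Directly-follows process discovery and PNML serialization.

The miner builds the directly-follows graph (DFG) over event names, with
traces padded by START/END, and converts it into a Petri net: one labeled
transition per event name, one place per retained directly-follows pair
(observed count >= ``frequency_threshold``) connecting the pair's
transitions, a source place feeding START and a sink place fed by END.
An OTHER transition is always present so unseen event names at replay time
have a routing target.  Transitions left without inputs (all incoming pairs
pruned) are connected from the source place, and without outputs to the
sink, preserving the structural invariant that every transition has at
least one input and one output place.

Discovery is deterministic: same log, same net, same canonical ordering.
Externally mined nets can be substituted through :func:`read_pnml`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = ["PetriNet", "discover", "write_pnml", "read_pnml", "to_dot",
           "START", "END", "OTHER", "SOURCE", "SINK"]

START, END, OTHER = "__START__", "__END__", "__OTHER__"
SOURCE, SINK = "source", "sink"


@dataclass
class PetriNet:
    """A place/transition net with labeled transitions and initial marking.

    ``places`` is the canonical place order used for every feature vector
    derived from this net.  Arcs connect place ids and transition labels
    (the two namespaces are disjoint by construction).
    """

    places: list = field(default_factory=list)
    transitions: list = field(default_factory=list)
    arcs: set = field(default_factory=set)
    initial_marking: dict = field(default_factory=dict)
    final_place: str = SINK

    def __post_init__(self):
        self._rebuild_index()

    def _rebuild_index(self):
        self._place_set = set(self.places)
        self._in = {t: [] for t in self.transitions}
        self._out = {t: [] for t in self.transitions}
        for a, b in sorted(self.arcs):
            if a in self._place_set:
                self._in[b].append(a)
            else:
                self._out[a].append(b)

    def in_places(self, t: str) -> list:
        return self._in[t]

    def out_places(self, t: str) -> list:
        return self._out[t]

    def validate(self) -> None:
        for a, b in self.arcs:
            if (a in self._place_set) == (b in self._place_set):
                raise ValueError(f"arc {a}->{b} is not bipartite")
        for t in self.transitions:
            if not self._in[t] or not self._out[t]:
                raise ValueError(f"transition {t} lacks input or output places")
        if sum(self.initial_marking.values()) != 1:
            raise ValueError("initial marking must hold exactly one token (source place)")

    def equivalent(self, other: "PetriNet") -> bool:
        return (
            self.places == other.places
            and sorted(self.transitions) == sorted(other.transitions)
            and self.arcs == other.arcs
            and self.initial_marking == other.initial_marking
        )


def pair_place(a: str, b: str) -> str:
    return f"p__{a}__{b}"


def discover(train_traces, frequency_threshold: int = 1) -> PetriNet:
    """Mine a Petri net from the training traces' directly-follows relation."""
    if not train_traces:
        raise ValueError("cannot discover a model from an empty log")
    if frequency_threshold < 1:
        raise ValueError("frequency_threshold must be >= 1")

    dfg = Counter()
    names = set()
    for trace in train_traces:
        seq = [START] + [e.name for e in trace.events] + [END]
        names.update(seq)
        dfg.update(zip(seq, seq[1:]))

    retained = sorted(p for p, c in dfg.items() if c >= frequency_threshold)
    transitions = sorted(names | {OTHER})
    places = [SOURCE] + [pair_place(a, b) for a, b in retained] + [SINK]

    arcs = {(SOURCE, START), (END, SINK)}
    for a, b in retained:
        arcs.add((a, pair_place(a, b)))
        arcs.add((pair_place(a, b), b))
    # keep the structural invariant for orphaned transitions (incl. OTHER)
    have_in = {b for (_, b) in arcs if b in set(transitions)}
    have_out = {a for (a, _) in arcs if a in set(transitions)}
    for t in transitions:
        if t not in have_in:
            arcs.add((SOURCE, t))
        if t not in have_out:
            arcs.add((t, SINK))

    net = PetriNet(
        places=places,
        transitions=transitions,
        arcs=arcs,
        initial_marking={SOURCE: 1},
    )
    net.validate()
    return net


# ---------------------------------------------------------------------------
# PNML (ISO/IEC 15909-2) serialization

_PT_NET = "http://www.pnml.org/version-2009/grammar/ptnet"


def write_pnml(net: PetriNet, path, alphas: dict | None = None) -> None:
    """Write the net as PNML; decay rates go into a toolspecific block."""
    from lxml import etree

    net.validate()
    root = etree.Element("pnml")
    n = etree.SubElement(root, "net", id="net1", type=_PT_NET)
    page = etree.SubElement(n, "page", id="page1")
    for p in net.places:
        pe = etree.SubElement(page, "place", id=f"pl__{p}")
        name = etree.SubElement(pe, "name")
        etree.SubElement(name, "text").text = p
        if net.initial_marking.get(p):
            mk = etree.SubElement(pe, "initialMarking")
            etree.SubElement(mk, "text").text = str(net.initial_marking[p])
    for t in net.transitions:
        te = etree.SubElement(page, "transition", id=f"tr__{t}")
        name = etree.SubElement(te, "name")
        etree.SubElement(name, "text").text = t
    place_set = set(net.places)
    for i, (a, b) in enumerate(sorted(net.arcs)):
        src = f"pl__{a}" if a in place_set else f"tr__{a}"
        tgt = f"pl__{b}" if b in place_set else f"tr__{b}"
        etree.SubElement(page, "arc", id=f"a{i}", source=src, target=tgt)
    if alphas:
        tool = etree.SubElement(n, "toolspecific", tool="hfreadmit", version="1.0")
        for p, a in alphas.items():
            etree.SubElement(tool, "decay", place=p, alpha=repr(float(a)))
    etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def read_pnml(path) -> tuple[PetriNet, dict]:
    """Read a PNML net (ours or externally mined); returns (net, alphas)."""
    from lxml import etree

    try:
        root = etree.parse(str(path)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed PNML file {path}: {exc}") from exc

    def local(tag):
        return tag.rsplit("}", 1)[-1]

    id2name, places, transitions, arcs_raw, marking = {}, [], [], [], {}
    alphas: dict = {}
    for el in root.iter():
        tag = local(el.tag)
        if tag in ("place", "transition"):
            pid = el.get("id")
            texts = [c for c in el.iter() if local(c.tag) == "text"]
            name_el = None
            for c in el:
                if local(c.tag) == "name":
                    name_el = c
            label = pid
            if name_el is not None:
                for c in name_el.iter():
                    if local(c.tag) == "text" and c.text:
                        label = c.text
            label = label.removeprefix("pl__").removeprefix("tr__")
            id2name[pid] = label
            (places if tag == "place" else transitions).append(label)
            if tag == "place":
                for c in el:
                    if local(c.tag) == "initialMarking":
                        for tx in c.iter():
                            if local(tx.tag) == "text" and tx.text:
                                marking[label] = int(tx.text)
        elif tag == "arc":
            arcs_raw.append((el.get("source"), el.get("target")))
        elif tag == "decay":
            alphas[el.get("place")] = float(el.get("alpha"))
    if not marking:
        raise ValueError(f"PNML net in {path} lacks an initial marking")
    arcs = {(id2name[s], id2name[t]) for s, t in arcs_raw}
    net = PetriNet(places=places, transitions=transitions, arcs=arcs, initial_marking=marking)
    return net, alphas


def to_dot(net: PetriNet) -> str:
    """GraphViz DOT export for visual inspection of the discovered model."""
    lines = ["digraph petrinet {", "  rankdir=LR;"]
    for p in net.places:
        lines.append(f'  "{p}" [shape=circle,label=""];')
    for t in net.transitions:
        lines.append(f'  "{t}" [shape=box];')
    for a, b in sorted(net.arcs):
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines)
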