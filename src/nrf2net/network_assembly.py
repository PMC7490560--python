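"""Y2H matrix scoring, conditional-affinity classification and network export.

Evidence layers from the interaction screens (Y2H growth calls, co-IP
confirmation flags, FCCS and scaled DULIP dissociation constants in wild-type
and KEAP1-null cells, reporter-screen functional classes) are merged into one
record per partner, edges are weighted by normalised binding affinity, and
the resulting binary interaction network is exported in Cytoscape-readable
formats (GraphML, SIF, node/edge TSV tables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Y2HCall",
    "Y2HScore",
    "InteractionRecord",
    "score_y2h_matrix",
    "classify_conditional_affinity",
    "integrate_evidence",
    "compute_edge_weights",
    "export_network",
    "import_graphml",
    "summarise_network",
]

NA = "NA"  # explicit absent marker used in exports
HUB = "NRF2"


@dataclass(frozen=True)
class Y2HCall:
    """One growth call: a partner against one NRF2 fragment, one assay
    replicate, one reporter gene."""

    bait: str
    prey: str
    nrf2_fragment: str
    assay_replicate: int | str
    reporter: str
    growth: bool
    autoactivator: bool = False


@dataclass
class Y2HScore:
    """Scored matrix: positive pairs, per-partner domain profiles, and the
    pairs that could not be scored."""

    positive_pairs: set[tuple[str, str]]
    domain_profiles: dict[str, set[str]]
    untested_incomplete: set[tuple[str, str]]
    excluded_autoactivators: set[tuple[str, str]]

    @property
    def positive_partners(self) -> set[str]:
        return {p for p, _ in self.positive_pairs}


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


def score_y2h_matrix(calls: Iterable[Y2HCall | Mapping]) -> Y2HScore:
    """Score a Y2H matrix with the reproducible-in-two rule.

    A (partner, fragment) pair is positive iff growth was observed — on
    either reporter (ADE2 or HIS3) — in at least two independent assay
    replicates, and neither clone auto-activates.  Pairs with a single
    replicate are reported as untested-incomplete, never positive.
    """
    # growth per (pair, replicate): OR over reporters
    growth: dict[tuple[str, str], dict] = {}
    auto_pairs: set[tuple[str, str]] = set()
    for call in calls:
        if isinstance(call, Mapping):
            call = Y2HCall(**{k: call[k] for k in (
                "bait", "prey", "nrf2_fragment", "assay_replicate",
                "reporter", "growth", "autoactivator")})
        partner = _norm(call.prey) if _norm(call.prey) != HUB else _norm(call.bait)
        pair = (partner, call.nrf2_fragment)
        rep = growth.setdefault(pair, {})
        rep[call.assay_replicate] = rep.get(call.assay_replicate, False) or bool(call.growth)
        if call.autoactivator:
            auto_pairs.add(pair)

    positive: set[tuple[str, str]] = set()
    incomplete: set[tuple[str, str]] = set()
    excluded: set[tuple[str, str]] = set()
    for pair, reps in growth.items():
        if len(reps) < 2:
            incomplete.add(pair)
            continue
        reproducible = sum(reps.values()) >= 2
        if pair in auto_pairs:
            if reproducible:
                excluded.add(pair)
            continue
        if reproducible:
            positive.add(pair)
    profiles: dict[str, set[str]] = {}
    for partner, fragment in positive:
        profiles.setdefault(partner, set()).add(fragment)
    return Y2HScore(
        positive_pairs=positive,
        domain_profiles=profiles,
        untested_incomplete=incomplete,
        excluded_autoactivators=excluded,
    )


def classify_conditional_affinity(
    kd_wt: float, kd_ko: float, threshold: float = 1.25
) -> str:
    """Classify the KEAP1-null affinity change of one partner.

    ``ratio = kd_ko / kd_wt``; strictly more than ``threshold``-fold weaker
    binding in the knockout is a ``loss`` of affinity, strictly more than
    ``threshold``-fold stronger binding a ``gain``; the boundary (ratio
    exactly equal to the threshold) is ``unchanged``.
    """
    if kd_wt <= 0 or kd_ko <= 0:
        raise ValueError("dissociation constants must be positive")
    ratio = kd_ko / kd_wt
    if ratio > threshold:
        return "loss"
    if ratio < 1.0 / threshold:
        return "gain"
    return "unchanged"


@dataclass
class InteractionRecord:
    """Integrated evidence for one binary partner of the hub protein."""

    partner: str
    domains_bound: set[str] = field(default_factory=set)
    y2h_positive: bool = False
    coip_confirmed: bool | None = None
    kd_fccs_nM: float | None = None
    kd_dulip_scaled_wt_nM: float | None = None
    kd_dulip_scaled_ko_nM: float | None = None
    affinity_fold_change: float | None = None
    conditional_class: str | None = None
    functional_class: tuple[str, ...] | None = None
    annotation: str = "other"
    known_partner: bool = False


def integrate_evidence(
    y2h: Y2HScore | None = None,
    coip_flags: Mapping[str, bool] | None = None,
    fccs_kd_nM: Mapping[str, float] | None = None,
    dulip_kd_wt_nM: Mapping[str, float] | None = None,
    dulip_kd_ko_nM: Mapping[str, float] | None = None,
    functional_classes: Mapping[str, Sequence[str]] | None = None,
    annotations: Mapping[str, str] | None = None,
    known_partners: Iterable[str] = (),
    conditional_threshold: float = 1.25,
) -> list[InteractionRecord]:
    """Join all evidence layers into one record per partner.

    Partner identifiers are case-normalised gene symbols.  Layers a partner
    is absent from stay ``None`` (explicit absent markers in exports).
    Duplicate symbols that collide after normalisation raise a hard error.
    """

    def norm_map(m: Mapping | None) -> dict:
        if not m:
            return {}
        out: dict = {}
        for k, v in m.items():
            nk = _norm(k)
            if nk in out:
                raise ValueError(f"conflicting duplicate records for partner {nk!r}")
            out[nk] = v
        return out

    coip = norm_map(coip_flags)
    fccs = norm_map(fccs_kd_nM)
    dulip_wt = norm_map(dulip_kd_wt_nM)
    dulip_ko = norm_map(dulip_kd_ko_nM)
    func = norm_map(functional_classes)
    annot = norm_map(annotations)
    known = {_norm(k) for k in known_partners}
    y2h_partners = {_norm(p) for p in (y2h.positive_partners if y2h else set())}
    profiles = {_norm(p): set(d) for p, d in (y2h.domain_profiles if y2h else {}).items()}

    partners = sorted(
        y2h_partners | set(coip) | set(fccs) | set(dulip_wt) | set(dulip_ko) | set(func)
    )
    records = []
    for p in partners:
        rec = InteractionRecord(
            partner=p,
            domains_bound=profiles.get(p, set()),
            y2h_positive=p in y2h_partners,
            coip_confirmed=coip.get(p),
            kd_fccs_nM=fccs.get(p),
            kd_dulip_scaled_wt_nM=dulip_wt.get(p),
            kd_dulip_scaled_ko_nM=dulip_ko.get(p),
            functional_class=tuple(func[p]) if p in func else None,
            annotation=annot.get(p, "other"),
            known_partner=p in known,
        )
        if rec.kd_dulip_scaled_wt_nM and rec.kd_dulip_scaled_ko_nM:
            rec.affinity_fold_change = rec.kd_dulip_scaled_ko_nM / rec.kd_dulip_scaled_wt_nM
            rec.conditional_class = classify_conditional_affinity(
                rec.kd_dulip_scaled_wt_nM, rec.kd_dulip_scaled_ko_nM,
                threshold=conditional_threshold,
            )
        records.append(rec)
    return records


def compute_edge_weights(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    """Affinity edge weights: per assay, min-max-normalised log10 K_d across
    partners, averaged over the assays available for each edge.

    Weight 0 is the strongest binder, 1 the weakest.  If all partners share
    one K_d value in an assay the weights degenerate to the 0.5 convention
    and the edge is flagged.
    """
    assays = {
        "fccs": {r.partner: r.kd_fccs_nM for r in records if r.kd_fccs_nM},
        "dulip": {r.partner: r.kd_dulip_scaled_wt_nM for r in records
                  if r.kd_dulip_scaled_wt_nM},
    }
    norm: dict[str, dict[str, tuple[float, bool]]] = {}
    for assay, kds in assays.items():
        finite = {p: v for p, v in kds.items() if math.isfinite(v)}
        if not finite:
            norm[assay] = {}
            continue
        logs = {p: math.log10(v) for p, v in finite.items()}
        lo, hi = min(logs.values()), max(logs.values())
        if hi == lo:
            norm[assay] = {p: (0.5, True) for p in logs}
        else:
            norm[assay] = {p: ((x - lo) / (hi - lo), False) for p, x in logs.items()}
    rows = []
    for rec in records:
        vals, degenerate, evidence = [], False, []
        for assay in ("fccs", "dulip"):
            if rec.partner in norm[assay]:
                v, d = norm[assay][rec.partner]
                vals.append(v)
                degenerate = degenerate or d
                evidence.append(assay)
        if not vals:
            continue
        rows.append(
            {
                "partner": rec.partner,
                "weight": float(np.mean(vals)),
                "evidence": "+".join(evidence),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows, columns=["partner", "weight", "evidence", "degenerate"])


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

_FORMATS = ("graphml", "sif", "tsv")


def _record_attrs(rec: InteractionRecord) -> dict:
    return {
        "annotation": rec.annotation,
        "functional_class": "|".join(rec.functional_class) if rec.functional_class else NA,
        "conditional_class": rec.conditional_class or NA,
        "known_partner": bool(rec.known_partner),
        "y2h_positive": bool(rec.y2h_positive),
        "coip_confirmed": NA if rec.coip_confirmed is None else str(bool(rec.coip_confirmed)),
        "domains_bound": "|".join(sorted(rec.domains_bound)) if rec.domains_bound else NA,
    }


def build_graph(records: Sequence[InteractionRecord],
                edges: pd.DataFrame | None = None) -> nx.Graph:
    """Star graph around the hub with full node/edge attribute sets."""
    if edges is None:
        edges = compute_edge_weights(records)
    g = nx.Graph()
    g.add_node(HUB, annotation="bZIP_TF", functional_class=NA, conditional_class=NA,
               known_partner=True, y2h_positive=False, coip_confirmed=NA,
               domains_bound=NA)
    weights = {row["partner"]: row for _, row in edges.iterrows()}
    for rec in records:
        g.add_node(rec.partner, **_record_attrs(rec))
        attrs = {"relationship": "pp"}
        if rec.partner in weights:
            attrs["weight"] = float(weights[rec.partner]["weight"])
            attrs["evidence"] = str(weights[rec.partner]["evidence"])
        else:
            attrs["evidence"] = NA
        g.add_edge(HUB, rec.partner, **attrs)
    return g


def export_network(
    records: Sequence[InteractionRecord],
    edges: pd.DataFrame | None = None,
    fmt: str = "graphml",
    path: str | Path = "network.graphml",
) -> Path:
    """Write the network as GraphML, SIF or node/edge TSV tables.

    ``tsv`` writes ``<stem>.nodes.tsv`` and ``<stem>.edges.tsv`` and returns
    the node-table path.
    """
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {_FORMATS}")
    path = Path(path)
    g = build_graph(records, edges)
    if fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
        return path
    if fmt == "sif":
        lines = [f"{u}\tpp\t{v}" for u, v in sorted(g.edges())]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return path
    nodes = pd.DataFrame(
        [{"node": n, **g.nodes[n]} for n in sorted(g.nodes)]
    )
    edge_rows = [{"source": u, "target": v, **g.edges[u, v]} for u, v in sorted(g.edges())]
    node_path = path.with_suffix(".nodes.tsv")
    edge_path = path.with_suffix(".edges.tsv")
    nodes.to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(edge_rows).to_csv(edge_path, sep="\t", index=False)
    return node_path


def import_graphml(path: str | Path) -> nx.Graph:
    """Round-trip companion of :func:`export_network` for GraphML files."""
    return nx.read_graphml(Path(path))


def summarise_network(records: Sequence[InteractionRecord]) -> dict:
    """Counts and percentages by evidence layer, conditional and functional
    class; percentages always carry explicit numerator/denominator."""

    def pct(num: int, den: int) -> dict:
        return {"n": num, "of": den, "pct": round(100.0 * num / den, 1) if den else 0.0}

    n = len(records)
    coip_tested = [r for r in records if r.coip_confirmed is not None]
    coip_pos = [r for r in coip_tested if r.coip_confirmed]
    conditional = [r for r in records if r.conditional_class in ("gain", "loss")]
    by_cond: dict[str, int] = {"gain": 0, "loss": 0, "unchanged": 0}
    for r in records:
        if r.conditional_class in by_cond:
            by_cond[r.conditional_class] += 1
    by_func: dict[str, int] = {}
    for r in records:
        for cls in r.functional_class or ():
            by_func[cls] = by_func.get(cls, 0) + 1
    by_annot: dict[str, int] = {}
    for r in records:
        by_annot[r.annotation] = by_annot.get(r.annotation, 0) + 1
    return {
        "n_partners": n,
        "y2h_positive": sum(r.y2h_positive for r in records),
        "coip_confirmed": pct(len(coip_pos), len(coip_tested)),
        "quantified_fccs": sum(r.kd_fccs_nM is not None for r in records),
        "quantified_dulip": sum(r.kd_dulip_scaled_wt_nM is not None for r in records),
        "conditional_partners": len(conditional),
        "by_conditional_class": by_cond,
        "by_functional_class": by_func,
        "by_annotation": by_annot,
    }
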