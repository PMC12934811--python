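"""Drug-identity harmonization across studies.

Raw drug names coming from different studies are merged into shared identities
via an alias graph: nodes are normalized names, edges come either from exact
normalized-form matches, from study-provided aliases, or from a curated synonym
table. Connected components become drug identities. The merge iterates to a
fixpoint (each pass can expose newly shared aliases), and components whose
members carry contradictory curated canonical names are split back along
curated edges and flagged for review rather than silently merged.

Also provides mechanism/target annotation from prioritized sources and the
minimum-study inclusion filter used before cross-study integration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import ConfigError, ValidationError
from .screen_data import DrugAnnotation, ScreenDataset

_PUNCT = re.compile(r"[^a-z0-9]+")


def default_salt_suffixes() -> frozenset[str]:
    text = (
        importlib_resources.files("multiscreen.resources")
        .joinpath("salts.txt")
        .read_text()
    )
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def normalize_drug_name(raw: str, salt_suffixes: Iterable[str] | None = None) -> str:
    """Deterministic normalized form: lowercase, punctuation collapsed,
    trailing salt/solvate words stripped."""
    if not raw or not raw.strip():
        raise ValidationError("empty drug name")
    salts = (
        default_salt_suffixes() if salt_suffixes is None else {s.lower() for s in salt_suffixes}
    )
    words = raw.strip().lower().split()
    while len(words) > 1 and words[-1].strip(",.;") in salts:
        words.pop()
    return _PUNCT.sub("", "".join(words))


@dataclass
class MergeResult:
    mapping: dict[str, str]  # raw name -> drug_id
    conflicts: pd.DataFrame = field(default_factory=pd.DataFrame)
    log: list = field(default_factory=list)


def _component_split(graph: nx.Graph, canonical_of: Mapping[str, str], strict: bool):
    """Split components with contradictory curated canonicals along curated edges."""
    conflicts = []
    final_components = []
    for comp in nx.connected_components(graph):
        canon = {canonical_of[n] for n in comp if n in canonical_of}
        if len(canon) <= 1:
            final_components.append(set(comp))
            continue
        # contradictory curation: keep only curated edges, re-split
        sub = graph.subgraph(comp)
        curated = nx.Graph()
        curated.add_nodes_from(sub.nodes)
        curated.add_edges_from(
            (u, v) for u, v, d in sub.edges(data=True) if d.get("source") == "curated"
        )
        for piece in nx.connected_components(curated):
            piece_canon = {canonical_of[n] for n in piece if n in canonical_of}
            if len(piece_canon) > 1:
                msg = (
                    f"unresolvable curated conflict among {sorted(piece)}: "
                    f"canonicals {sorted(piece_canon)}"
                )
                if strict:
                    raise ValidationError(msg)
                conflicts.append(
                    {"members": "|".join(sorted(piece)), "canonicals": "|".join(sorted(piece_canon)), "resolved": False}
                )
            final_components.append(set(piece))
        conflicts.append(
            {
                "members": "|".join(sorted(comp)),
                "canonicals": "|".join(sorted(canon)),
                "resolved": True,
            }
        )
    return final_components, conflicts


def merge_drug_identities(
    names_by_study: Mapping[str, Iterable[str]],
    synonym_table: pd.DataFrame | None = None,
    salt_suffixes: Iterable[str] | None = None,
    strict: bool = False,
) -> MergeResult:
    """Merge raw drug names into identities via the alias graph fixpoint.

    Parameters
    ----------
    names_by_study
        Raw drug names per study (order-independent).
    synonym_table
        Optional curated table with columns ``alias`` and ``canonical``
        (and optionally ``source``).
    """
    raw_names = sorted({n for names in names_by_study.values() for n in names})
    norm = {r: normalize_drug_name(r, salt_suffixes) for r in raw_names}

    graph = nx.Graph()
    graph.add_nodes_from(sorted(set(norm.values())))
    canonical_of: dict[str, str] = {}
    if synonym_table is not None and len(synonym_table):
        for row in synonym_table.to_dict("records"):
            a = normalize_drug_name(str(row["alias"]), salt_suffixes)
            c = normalize_drug_name(str(row["canonical"]), salt_suffixes)
            graph.add_edge(a, c, source="curated")
            canonical_of[a] = c
            canonical_of[c] = c

    log = [f"{len(raw_names)} raw names -> {graph.number_of_nodes()} normalized nodes"]

    # fixpoint: components sharing any alias (raw or canonical form) merge
    while True:
        alias_owner: dict[str, str] = {}
        new_edges = []
        for comp in nx.connected_components(graph):
            rep = min(comp)
            aliases = set(comp)
            for r, n in norm.items():
                if n in comp:
                    aliases.add(normalize_drug_name(r, salt_suffixes))
            for a in aliases:
                if a in alias_owner and alias_owner[a] != rep:
                    new_edges.append((alias_owner[a], rep))
                else:
                    alias_owner[a] = rep
        added = 0
        for u, v in new_edges:
            if not graph.has_edge(u, v):
                graph.add_edge(u, v, source="shared-alias")
                added += 1
        if added == 0:
            break
        log.append(f"merge pass added {added} shared-alias edges")

    components, conflicts = _component_split(graph, canonical_of, strict=strict)

    mapping: dict[str, str] = {}
    node_to_id: dict[str, str] = {}
    for comp in components:
        canon = sorted({canonical_of[n] for n in comp if n in canonical_of})
        drug_id = canon[0] if len(canon) == 1 else min(comp)
        for n in comp:
            node_to_id[n] = drug_id
    for r in raw_names:
        mapping[r] = node_to_id[norm[r]]
    log.append(f"{len(raw_names)} raw names merged into {len(set(mapping.values()))} identities")
    return MergeResult(mapping=mapping, conflicts=pd.DataFrame(conflicts), log=log)


def annotate_mechanisms(
    drugs: Mapping[str, DrugAnnotation],
    mechanism_table: pd.DataFrame,
    priority: list[str] | None = None,
    salt_suffixes: Iterable[str] | None = None,
) -> dict[str, DrugAnnotation]:
    """Attach mechanism/target annotations, matching on any alias.

    Mechanisms are ordered by source priority, then by frequency across hits;
    target sets are unioned. Drugs with no hit keep an empty mechanism list
    (``unannotated`` flag).
    """
    priority = priority or []
    tbl = mechanism_table.copy()
    tbl["_key"] = [normalize_drug_name(a, salt_suffixes) for a in tbl["alias"].astype(str)]
    by_key = dict(tuple(tbl.groupby("_key")))
    out = {}
    for drug_id, ann in drugs.items():
        keys = {normalize_drug_name(a, salt_suffixes) for a in ann.aliases}
        hits = pd.concat([by_key[k] for k in sorted(keys) if k in by_key], axis=0) if any(
            k in by_key for k in keys
        ) else None
        mechanisms: list[str] = []
        targets = set(ann.targets)
        if hits is not None:
            def rank(source: str) -> int:
                return priority.index(source) if source in priority else len(priority)

            freq = hits["mechanism"].value_counts()
            scored = sorted(
                {
                    (rank(str(r.get("source", ""))), -freq[r["mechanism"]], r["mechanism"])
                    for r in hits.to_dict("records")
                }
            )
            for _, _, mech in scored:
                if mech not in mechanisms:
                    mechanisms.append(mech)
            for t in hits.get("targets", pd.Series(dtype=str)).dropna():
                targets.update(x for x in str(t).split("|") if x)
        out[drug_id] = DrugAnnotation(
            drug_id=drug_id,
            canonical_name=ann.canonical_name,
            aliases=set(ann.aliases),
            mechanisms=mechanisms or list(ann.mechanisms),
            targets=targets,
            soc_diseases=set(ann.soc_diseases),
        )
    return out


def filter_min_studies(ds: ScreenDataset, min_studies: int = 3):
    """Keep only drugs screened in at least `min_studies` distinct studies.

    Returns (filtered dataset, stats dict with kept/dropped counts).
    """
    if min_studies < 1:
        raise ConfigError("min_studies must be >= 1")
    occ = ds.records.groupby("drug_id")["study_id"].nunique()
    kept = occ.index[occ >= min_studies]
    out = ds.subset_drugs(kept)
    stats = {
        "kept_drugs": int(len(kept)),
        "dropped_drugs": int((occ < min_studies).sum()),
        "kept_records": len(out),
        "dropped_records": len(ds) - len(out),
    }
    return out, stats
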