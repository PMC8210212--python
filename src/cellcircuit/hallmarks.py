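"""Map signaling circuits to cancer hallmarks via their effector genes.

Hallmarks are the canonical acquired capabilities of tumors (resisting cell
death, sustaining proliferative signaling, inducing angiogenesis, ...).  A
circuit inherits the union of the hallmarks annotated to the genes of its
effector node; summaries partition each group's significant circuits into a
common core (significant in every group) and group-specific extras, and
report two percentage views: share of the group's significant circuits, and
share of all circuits annotated to the hallmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .pathways import Circuit

CANONICAL_HALLMARKS = (
    "Sustaining proliferative signaling",
    "Evading growth suppressors",
    "Resisting cell death",
    "Enabling replicative immortality",
    "Inducing angiogenesis",
    "Activating invasion and metastasis",
    "Genome instability and mutation",
    "Tumor promoting inflammation",
    "Deregulating cellular energetics",
    "Avoiding immune destruction",
)


def normalize_hallmark(name: str) -> str:
    """Collapse whitespace and strip; hallmark names compare case-insensitively."""
    return " ".join(name.split())


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read gene sets from GMT (set name, description, member symbols).

    Returns hallmark name -> set of upper-cased gene symbols.  Sets whose
    names normalize to the same string (case/whitespace) are merged.
    """
    sets: dict[str, set[str]] = {}
    canon: dict[str, str] = {}  # casefolded -> first-seen display name
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need >= 3 fields")
            name = normalize_hallmark(fields[0])
            key = name.casefold()
            display = canon.setdefault(key, name)
            sets.setdefault(display, set()).update(
                g.strip().upper() for g in fields[2:] if g.strip()
            )
    return {name: frozenset(genes) for name, genes in sets.items()}


def gene_hallmarks(gmt: Mapping[str, frozenset[str]]) -> dict[str, frozenset[str]]:
    """Invert a GMT mapping into gene symbol -> set of hallmark names."""
    out: dict[str, set[str]] = {}
    for hallmark, genes in gmt.items():
        for g in genes:
            out.setdefault(g.upper(), set()).add(normalize_hallmark(hallmark))
    return {g: frozenset(h) for g, h in out.items()}


def annotate_circuits(
    circuits: Sequence[Circuit],
    ann: Mapping[str, frozenset[str]],
    node_gene_map: Mapping[str, Mapping[str, tuple[str, ...]]],
) -> dict[str, frozenset[str]]:
    """Circuit id -> hallmark set, inherited from the effector node's genes.

    ``ann`` maps gene symbol -> hallmarks (see :func:`gene_hallmarks`);
    ``node_gene_map`` maps pathway id -> node id -> genes.  Circuits whose
    effector genes are unannotated map to the empty set.
    """
    out: dict[str, frozenset[str]] = {}
    for c in circuits:
        genes = node_gene_map[c.pathway_id][c.effector_node]
        hallmarks: set[str] = set()
        for g in genes:
            hallmarks |= set(ann.get(str(g).upper(), ()))
        out[c.circuit_id] = frozenset(hallmarks)
    return out


@dataclass
class HallmarkSummary:
    """Common-vs-specific hallmark breakdown across cell groups.

    counts            hallmark x [common, <group> extra ...] circuit counts
    pct_of_significant hallmark x group: percent of the group's significant
                      circuits annotated to the hallmark
    pct_of_annotated  hallmark x group: percent of all circuits annotated to
                      the hallmark that are significant in the group
    common / extras   the underlying circuit-id sets
    directions        circuit id -> group -> UP/DOWN for significant calls
    """

    counts: pd.DataFrame
    pct_of_significant: pd.DataFrame
    pct_of_annotated: pd.DataFrame
    common: frozenset[str]
    extras: dict[str, frozenset[str]]
    directions: dict[str, dict[str, str]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def hallmark_summary(
    diff_tables: Mapping[str, pd.DataFrame],
    circuit_hallmarks: Mapping[str, frozenset[str]],
) -> HallmarkSummary:
    """Summarize significant circuits per hallmark across groups.

    ``diff_tables`` maps group name -> differential result table (needs
    ``circuit_id``, ``significant`` and optionally ``direction`` columns).
    "Common" circuits are significant in every group; each group's "extra"
    set is its significant circuits minus the common core, so common plus
    extras partitions every group's significant set.  Only circuits with at
    least one hallmark annotation enter the counts.
    """
    if not diff_tables:
        raise ValueError("need at least one group")
    groups = list(diff_tables)

    sig: dict[str, set[str]] = {}
    directions: dict[str, dict[str, str]] = {}
    for g, table in diff_tables.items():
        called = table.loc[table["significant"], "circuit_id"]
        sig[g] = {c for c in called if circuit_hallmarks.get(c)}
        if "direction" in table.columns:
            for _, row in table.loc[table["significant"]].iterrows():
                directions.setdefault(row["circuit_id"], {})[g] = row["direction"]

    common = set.intersection(*sig.values()) if sig else set()
    extras = {g: frozenset(sig[g] - common) for g in groups}

    hallmarks = sorted(
        {h for hs in circuit_hallmarks.values() for h in hs},
        key=lambda h: (
            CANONICAL_HALLMARKS.index(h) if h in CANONICAL_HALLMARKS else 99,
            h,
        ),
    )

    def count(circuit_set: set[str] | frozenset[str], h: str) -> int:
        return sum(1 for c in circuit_set if h in circuit_hallmarks.get(c, ()))

    counts = pd.DataFrame(
        {
            "common": [count(common, h) for h in hallmarks],
            **{
                f"{g} extra": [count(extras[g], h) for h in hallmarks]
                for g in groups
            },
        },
        index=pd.Index(hallmarks, name="hallmark"),
    )

    n_annotated_total = {
        h: sum(1 for hs in circuit_hallmarks.values() if h in hs) for h in hallmarks
    }
    pct_sig = pd.DataFrame(index=counts.index, columns=groups, dtype=float)
    pct_ann = pd.DataFrame(index=counts.index, columns=groups, dtype=float)
    for g, table in diff_tables.items():
        n_sig_total = int(table["significant"].sum())
        for h in hallmarks:
            n_h = count(sig[g], h)
            pct_sig.loc[h, g] = 100.0 * n_h / n_sig_total if n_sig_total else 0.0
            pct_ann.loc[h, g] = (
                100.0 * n_h / n_annotated_total[h] if n_annotated_total[h] else 0.0
            )

    return HallmarkSummary(
        counts=counts,
        pct_of_significant=pct_sig,
        pct_of_annotated=pct_ann,
        common=frozenset(common),
        extras=extras,
        directions=directions,
        meta={
            "specific_definition": "significant-in-group minus common-to-all-groups",
            "groups": groups,
            "denominator_pct_of_significant": "all significant circuits in group",
            "denominator_pct_of_annotated": "all circuits annotated to hallmark",
        },
    )
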