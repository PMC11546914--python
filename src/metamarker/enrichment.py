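"""Pathway over-representation analysis (ORA) and marker-set combination.

Given a marker set and GMT-style pathway annotations, each pathway is tested
with the one-sided upper-tail hypergeometric distribution: drawing
``|markers|`` metabolites from a universe of the measured, annotated
metabolites, what is the probability of at least the observed number landing
in the pathway?  Benjamini-Hochberg FDR is applied across pathways.  The
universe is the measured-metabolite universe — only metabolites present in
the analyzed matrix count, both as draws and as pathway members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .screening import adjust_benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayAnnotation:
    pathway_id: str
    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class ORAResult:
    pathway_id: str
    name: str
    total: int
    hits: int
    p_value: float
    fdr: float


def read_annotation(path: str | Path) -> list[PathwayAnnotation]:
    """Parse a GMT-style file: ``id <tab> description <tab> member...``.

    Duplicate members within a line are collapsed with a warning; lines with
    no members are skipped with a warning.
    """
    out: list[PathwayAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected id<TAB>description[<TAB>members...]")
            pid, name, *members = parts
            members = [m for m in members if m]
            if not members:
                logger.warning("line %d: pathway %s has no members; skipped", lineno, pid)
                continue
            unique = frozenset(members)
            if len(unique) < len(members):
                logger.warning(
                    "line %d: pathway %s lists %d duplicate members",
                    lineno, pid, len(members) - len(unique),
                )
            out.append(PathwayAnnotation(pid, name, unique))
    return out


def write_annotation(annotations: list[PathwayAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            fh.write("\t".join([ann.pathway_id, ann.name, *sorted(ann.members)]) + "\n")


def ora(
    markers: set[str],
    annotations: list[PathwayAnnotation],
    universe: set[str],
) -> list[ORAResult]:
    """One-sided hypergeometric over-representation test per pathway.

    Pathway member sets are intersected with the universe before testing;
    ``p = P(X >= hits)`` for X hypergeometric with population ``|universe|``,
    ``|pathway ∩ universe|`` successes and ``|markers|`` draws.  Results are
    sorted by p-value.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    markers = set(markers)
    if not markers <= universe:
        raise ValueError(
            f"markers outside the universe: {sorted(markers - universe)[:5]}"
        )
    rows = []
    for ann in annotations:
        in_universe = ann.members & universe
        total = len(in_universe)
        hits = len(in_universe & markers)
        p = float(hypergeom.sf(hits - 1, len(universe), total, len(markers)))
        rows.append((ann, total, hits, min(p, 1.0)))
    fdr = adjust_benjamini_hochberg([r[3] for r in rows]) if rows else []
    results = [
        ORAResult(ann.pathway_id, ann.name, total, hits, p, float(q))
        for (ann, total, hits, p), q in zip(rows, fdr)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.pathway_id))


def ora_table(results: list[ORAResult]) -> pd.DataFrame:
    """Tabular view with the conventional pathway/total/hits/p/FDR columns."""
    return pd.DataFrame(
        [(r.pathway_id, r.name, r.total, r.hits, r.p_value, r.fdr) for r in results],
        columns=["pathway", "name", "total", "hits", "p", "fdr"],
    )


def combine_marker_sets(
    primary: set[str], secondary: set[str]
) -> tuple[set[str], set[str]]:
    """Union (for combined ORA) and intersection (dual-status metabolites)."""
    primary, secondary = set(primary), set(secondary)
    return primary | secondary, primary & secondary
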