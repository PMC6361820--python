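"""Site-level statistics: signatures, coordination, distances, co-activity.

These are the descriptive statistics usually reported for a zinc-site
database: the residue composition "signature" of each site (C4, C3H1, ...),
the coordination number of single-zinc sites (waters included), the
distributions of metal-ligand distances per liganding element, the table of
co-active metals found alongside zinc in multi-metal sites, and a Fisher
exact test for whether multi-metal sites are enriched in enzymes.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from collections.abc import Sequence

import numpy as np
from scipy import stats

from znsites.detection import BindingSite

__all__ = [
    "DistanceStats",
    "CoactiveTable",
    "residue_signature",
    "signature_counts",
    "coordination_mode",
    "distance_statistics",
    "coactive_summary",
    "is_enzymatic",
    "enzymatic_enrichment",
]


@dataclasses.dataclass(frozen=True)
class DistanceStats:
    """Mean/spread of metal-ligand distances for one liganding element."""

    element: str
    n: int
    mean: float
    sd: float


@dataclasses.dataclass
class CoactiveTable:
    """Per-element counts over multi-metal sites.

    ``counts`` maps element -> (atom count, site count).  For zinc the atom
    count is the number of *extra* zincs: a three-zinc site contributes +2.
    For other metals it is the number of atoms of that element found in
    multi-metal zinc sites.  ``histogram`` maps metals-per-site -> number
    of sites.
    """

    counts: dict[str, tuple[int, int]]
    histogram: dict[int, int]


def residue_signature(site: BindingSite) -> str:
    """Compact residue-composition descriptor, e.g. ``C4`` or ``C3H1``.

    One-letter codes of the protein liganding residues, alphabetically,
    each followed by its count.  Waters and other non-protein ligands are
    not part of the signature.
    """
    protein = site.protein_residues
    if not protein:
        raise ValueError("site has no protein liganding residues")
    counts = Counter(r.one_letter for r in protein)
    return "".join(f"{code}{n}" for code, n in sorted(counts.items()))


def signature_counts(sites: Sequence[BindingSite]) -> Counter[str]:
    """Signature frequency over a collection of sites (all or representative)."""
    return Counter(residue_signature(site) for site in sites)


def coordination_mode(site: BindingSite) -> int:
    """Coordination number of a single-zinc site, waters included."""
    if len(site.metals) != 1:
        raise ValueError("coordination mode is defined for single-zinc sites only")
    (zinc,) = site.metals
    return sum(1 for c in site.contacts if c.metal is zinc)


def distance_statistics(
    sites: Sequence[BindingSite], element: str, max_resolution: float = 3.0
) -> DistanceStats:
    """Distance distribution of one liganding element around zinc.

    Pools the contact distances of single-zinc sites from structures with
    resolution strictly better than ``max_resolution``, for contacts whose
    liganding atom has the given element; returns count, mean and sample
    (n-1) standard deviation.
    """
    distances = [
        c.distance
        for site in sites
        if len(site.metals) == 1
        and site.structure.resolution is not None
        and site.structure.resolution < max_resolution
        for c in site.contacts
        if c.atom.element == element
    ]
    if not distances:
        raise ValueError(f"no qualifying {element} contacts in the given sites")
    arr = np.asarray(distances)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return DistanceStats(element=element, n=len(arr), mean=float(arr.mean()), sd=sd)


def coactive_summary(sites: Sequence[BindingSite]) -> CoactiveTable:
    """Tabulate the metals co-occurring with zinc in multi-metal sites."""
    counts: dict[str, list[int]] = {}
    histogram: Counter[int] = Counter()
    for site in sites:
        histogram[len(site.metals)] += 1
        if len(site.metals) < 2:
            continue
        by_element = Counter(m.element for m in site.metals)
        for element, n in by_element.items():
            extra = n - 1 if element == "Zn" else n
            if extra == 0:
                continue
            entry = counts.setdefault(element, [0, 0])
            entry[0] += extra
            entry[1] += 1
    return CoactiveTable(
        counts={e: (c[0], c[1]) for e, c in sorted(counts.items())},
        histogram=dict(sorted(histogram.items())),
    )


def is_enzymatic(molecule_name: str) -> bool:
    """Heuristic enzyme flag: any whitespace token of the name ends in -ase."""
    return any(token.endswith("ase") for token in molecule_name.lower().split())


def enzymatic_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher exact test on the 2x2 table [[a, b], [c, d]].

    Rows are multi-metal vs zinc-only sites, columns enzymatic vs not.
    Returns (odds ratio, two-sided p); the p-value sums the hypergeometric
    probabilities of all tables with the observed margins that are no more
    probable than the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("every margin of the contingency table must be positive")
    odds_ratio, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds_ratio), float(p)
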