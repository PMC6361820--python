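"""Redundancy removal: 90%-identity chain clustering and site clustering.

The structure databank is massively redundant — hundreds of depositions of
carbonic anhydrase, for instance — so equivalent binding sites must be
collapsed before any unbiased statistics.  Chains are clustered by greedy
incremental clustering at 90% sequence identity (longest sequence seeds a
cluster, each following chain joins the first cluster whose representative
it matches, the CD-HIT strategy).  Two binding sites are then equivalent
when (i) they involve the same chain cluster(s), (ii) their liganding
residue types occur in the same order along the chain, and (iii) the
residues immediately flanking each liganding residue in sequence have the
same types.  Each site cluster is represented by the member from the
best-resolution structure.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

from Bio import Align

from znsites.detection import BindingSite

__all__ = [
    "ChainCluster",
    "SiteFingerprint",
    "SiteCluster",
    "pairwise_identity",
    "cluster_chains",
    "site_fingerprint",
    "cluster_sites",
    "zinc_chain_fasta",
]

ChainKey = tuple[str, str]  # (pdb id, chain id)

#: Fingerprint: sorted tuple of per-chain entries
#: (chain cluster id, liganding residue types in order, (prev, next) types).
SiteFingerprint = tuple[tuple[str, tuple[str, ...], tuple[tuple[str, str], ...]], ...]


@dataclasses.dataclass(eq=False)
class ChainCluster:
    id: str
    members: list[ChainKey]
    representative: ChainKey
    representative_sequence: str


@dataclasses.dataclass(eq=False)
class SiteCluster:
    id: str
    members: list[BindingSite]
    representative: BindingSite
    fingerprint: SiteFingerprint


def _aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity, matches over the shorter length.

    Scoring is match +1, mismatch 0, linear gap penalty -1; the identity is
    the number of identities in the best alignment divided by the length of
    the shorter sequence (the CD-HIT convention), so a fragment identical
    to part of a longer chain scores 1.0.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot compute identity of an empty sequence")
    alignment = _aligner().align(seq_a, seq_b)[0]
    identities = alignment.counts().identities
    return identities / min(len(seq_a), len(seq_b))


def cluster_chains(
    chains: Mapping[ChainKey, str] | Sequence[tuple[ChainKey, str]],
    threshold: float = 0.9,
) -> list[ChainCluster]:
    """Greedy incremental clustering of chain sequences.

    Chains are taken in order of decreasing length (ties by chain key);
    each joins the first existing cluster whose representative it matches
    at >= ``threshold`` identity, else it seeds a new cluster.  The result
    does not depend on the input ordering.
    """
    items = list(chains.items()) if isinstance(chains, Mapping) else list(chains)
    for key, seq in items:
        if not seq:
            raise ValueError(f"chain {key} has an empty sequence")
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))

    clusters: list[ChainCluster] = []
    for key, seq in items:
        for cluster in clusters:
            if pairwise_identity(seq, cluster.representative_sequence) >= threshold:
                cluster.members.append(key)
                break
        else:
            clusters.append(
                ChainCluster(
                    id=f"CC{len(clusters)}",
                    members=[key],
                    representative=key,
                    representative_sequence=seq,
                )
            )
    return clusters


def _cluster_lookup(clusters: Sequence[ChainCluster]) -> dict[ChainKey, ChainCluster]:
    return {key: cluster for cluster in clusters for key in cluster.members}


def site_fingerprint(
    site: BindingSite,
    chain_clusters: Mapping[ChainKey, ChainCluster] | Sequence[ChainCluster],
) -> SiteFingerprint:
    """Equivalence key of a binding site for cross-structure clustering.

    Built from the protein liganding residues only: residues are grouped by
    chain, each chain contributes (its chain-cluster id, the liganding
    residue one-letter types in sequence order, and for each liganding
    residue the types of its sequence neighbours at -1/+1, ``'-'`` at a
    terminus).  Chains are compared as a sorted multiset, so homodimer
    interface sites match regardless of chain labelling.
    """
    if not isinstance(chain_clusters, Mapping):
        chain_clusters = _cluster_lookup(chain_clusters)

    by_chain: dict[tuple[str, int], list] = {}
    for residue in site.protein_residues:
        by_chain.setdefault((residue.chain_id, residue.copy_index), []).append(residue)

    entries = []
    for (chain_id, copy_index), residues in by_chain.items():
        key = (site.structure.pdb_id, chain_id)
        if key not in chain_clusters:
            raise KeyError(f"liganding chain {key} is missing from the chain clusters")
        cluster_id = chain_clusters[key].id
        chain = site.structure.chain(chain_id)
        positions = {r.id: i for i, r in enumerate(chain.residues)}
        residues.sort(key=lambda r: (r.id[1], r.id[2]))
        types = tuple(r.one_letter for r in residues)
        neighbours = []
        for r in residues:
            i = positions[r.id]
            prev = chain.residues[i - 1].one_letter if i > 0 else "-"
            nxt = (
                chain.residues[i + 1].one_letter
                if i + 1 < len(chain.residues)
                else "-"
            )
            neighbours.append((prev, nxt))
        entries.append((cluster_id, types, tuple(neighbours)))
    return tuple(sorted(entries))


def cluster_sites(
    sites: Sequence[BindingSite],
    chain_clusters: Mapping[ChainKey, ChainCluster] | Sequence[ChainCluster],
) -> list[SiteCluster]:
    """Partition sites by fingerprint equality; pick best-resolution reps.

    The representative is the member whose structure has the lowest
    resolution value (structures without one, e.g. NMR models, rank last);
    ties break on the lexicographically smallest PDB id.
    """
    if not isinstance(chain_clusters, Mapping):
        chain_clusters = _cluster_lookup(chain_clusters)
    groups: dict[SiteFingerprint, list[BindingSite]] = {}
    for site in sites:
        groups.setdefault(site_fingerprint(site, chain_clusters), []).append(site)

    clusters = []
    for i, (fingerprint, members) in enumerate(sorted(groups.items())):
        representative = min(
            members,
            key=lambda s: (
                s.structure.resolution if s.structure.resolution is not None else float("inf"),
                s.structure.pdb_id,
            ),
        )
        clusters.append(
            SiteCluster(
                id=f"SC{i}",
                members=members,
                representative=representative,
                fingerprint=fingerprint,
            )
        )
    return clusters


def zinc_chain_fasta(sites: Sequence[BindingSite]) -> str:
    """FASTA of the chains that carry zinc-liganding residues.

    Headers are ``>pdbid_chainid``; each chain appears once even when it
    hosts several sites.  These are the sequences a sequence-search
    front-end over the site database would index.
    """
    records: dict[ChainKey, str] = {}
    for site in sites:
        for residue in site.protein_residues:
            key = (site.structure.pdb_id, residue.chain_id)
            if key not in records:
                records[key] = site.structure.chain(residue.chain_id).sequence
    lines = []
    for (pdb_id, chain_id), seq in sorted(records.items()):
        lines.append(f">{pdb_id}_{chain_id}")
        lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    return "\n".join(lines) + ("\n" if lines else "")
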