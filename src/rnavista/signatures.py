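"""Differential expression signature discovery.

Genes significant in at least one comparison are binned by their
cross-comparison call profile (e.g. up in A-vs-B and down in B-vs-C).
Each bin is summarized by a meta-gene: the per-sample median of the
member genes' z-scores. Bins are then merged agglomeratively — in every
iteration the pair of meta-genes with the highest Spearman correlation
is merged (gene sets unioned, the meta-gene recomputed from the union)
until no pair correlates above the user's SCC threshold. The surviving
gene groups are the differential expression signatures. A threshold of
1 performs no merges, keeping every profile as its own signature for
maximal resolution.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MasterGeneTable
from .stats import spearman

log = logging.getLogger("rnavista")

Profile = tuple[str, ...]   # one call in {"up", "down", "ns"} per comparison


@dataclass
class ProfileBin:
    """Genes sharing one cross-comparison differential profile."""

    profile: Profile
    member_genes: frozenset[str]
    meta_gene: np.ndarray       # one value per sample

    @property
    def label(self) -> str:
        return "|".join(self.profile)


@dataclass
class Signature:
    """One differential expression signature (merged profile bins)."""

    id: int                     # 1-based, ranked by descending size
    member_genes: frozenset[str]
    meta_gene: np.ndarray
    source_profiles: list[Profile]


@dataclass
class SignatureSet:
    signatures: list[Signature]
    scc_threshold: float
    merge_log: list[tuple[str, str, float]]   # (label_a, label_b, scc at merge)

    def assignment(self) -> pd.Series:
        """gene_id -> signature id."""
        pairs = [(g, s.id) for s in self.signatures for g in sorted(s.member_genes)]
        out = pd.Series({g: i for g, i in pairs}, dtype=int)
        out.index.name = "gene_id"
        return out


def bin_profiles(master: MasterGeneTable, comparisons: list[str] | None = None,
                 ) -> list[ProfileBin]:
    """Bin genes by their differential call profile across comparisons.

    Only genes significant (up or down) in at least one comparison are
    binned; "untested" entries collapse to "ns" within a profile. Bins
    are returned sorted by descending size then label.
    """
    comparisons = comparisons or master.comparisons
    if not comparisons:
        raise ValueError("need at least one comparison to bin profiles")
    call_df = pd.DataFrame(
        {c: master.calls(c).map(lambda v: "ns" if v == "untested" else v)
         for c in comparisons})
    sig_any = call_df.isin(["up", "down"]).any(axis=1)
    groups: dict[Profile, list[str]] = {}
    for gene, row in call_df[sig_any].iterrows():
        groups.setdefault(tuple(row), []).append(gene)
    z = master.zscores()
    bins = [
        ProfileBin(profile=prof, member_genes=frozenset(genes),
                   meta_gene=compute_metagene(genes, master, _z=z))
        for prof, genes in groups.items()
    ]
    bins.sort(key=lambda b: (-len(b.member_genes), b.label))
    return bins


def compute_metagene(genes, master: MasterGeneTable,
                     _z: pd.DataFrame | None = None) -> np.ndarray:
    """Per-sample median of the member genes' z-scores."""
    genes = list(genes)
    if not genes:
        raise ValueError("meta-gene of an empty gene list is undefined")
    z = _z if _z is not None else master.zscores()
    return z.loc[genes].median(axis=0).to_numpy(dtype=float)


def merge_signatures(bins: list[ProfileBin], master: MasterGeneTable,
                     scc_threshold: float = 0.9) -> SignatureSet:
    """Agglomerate profile bins into signatures by meta-gene correlation.

    Iteratively merges the pair of current meta-genes with the highest
    SCC while that SCC strictly exceeds ``scc_threshold``; after each
    merge the union's meta-gene is recomputed from the member genes'
    z-scores. Ties on the maximal SCC are broken by the lexicographically
    first pair of profile labels. With fewer than three samples rank
    correlations are meaningless, so the bins are returned unmerged with
    a warning.
    """
    if not -1.0 <= scc_threshold <= 1.0:
        raise ValueError("scc_threshold must lie in [-1, 1]")
    if not bins:
        return SignatureSet(signatures=[], scc_threshold=scc_threshold, merge_log=[])
    z = master.zscores()
    n_samples = z.shape[1]
    clusters: list[dict] = [
        {"labels": [b.label], "genes": set(b.member_genes), "meta": b.meta_gene,
         "profiles": [b.profile]}
        for b in bins
    ]
    merge_log: list[tuple[str, str, float]] = []
    if n_samples < 3 and len(clusters) > 1:
        log.warning("fewer than 3 samples: SCC undefined, returning bins unmerged")
    else:
        while len(clusters) > 1:
            best = None   # (scc, label_key, i, j)
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    a, b = clusters[i], clusters[j]
                    if np.ptp(a["meta"]) == 0 or np.ptp(b["meta"]) == 0:
                        continue   # constant meta-gene: SCC undefined, never merged
                    scc = spearman(a["meta"], b["meta"])
                    if np.isnan(scc):
                        continue
                    key = tuple(sorted(a["labels"] + b["labels"]))
                    cand = (scc, key, i, j)
                    if best is None or scc > best[0] or (
                            scc == best[0] and key < best[1]):
                        best = cand
            if best is None or best[0] <= scc_threshold:
                break
            scc, _, i, j = best
            a, b = clusters[i], clusters[j]
            merge_log.append((";".join(a["labels"]), ";".join(b["labels"]), scc))
            merged_genes = a["genes"] | b["genes"]
            merged = {
                "labels": sorted(a["labels"] + b["labels"]),
                "genes": merged_genes,
                "meta": compute_metagene(sorted(merged_genes), master, _z=z),
                "profiles": a["profiles"] + b["profiles"],
            }
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
            clusters.append(merged)
    clusters.sort(key=lambda c: (-len(c["genes"]), c["labels"]))
    signatures = [
        Signature(id=rank, member_genes=frozenset(c["genes"]),
                  meta_gene=c["meta"], source_profiles=list(c["profiles"]))
        for rank, c in enumerate(clusters, start=1)
    ]
    return SignatureSet(signatures=signatures, scc_threshold=scc_threshold,
                        merge_log=merge_log)


def discover_signatures(master: MasterGeneTable,
                        comparisons: list[str] | None = None,
                        scc_threshold: float = 0.9) -> SignatureSet:
    """Bin profiles then merge: the full signature pipeline."""
    bins = bin_profiles(master, comparisons)
    return merge_signatures(bins, master, scc_threshold)
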