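"""Pathway-level analyses: over-representation (ORA), upstream-regulator
analysis (URA), per-chromosome spatial enrichment, pairwise list overlap,
and the shared-genes network.

Conventions shared by all analyses here:

* the tested universe is the set of gene symbols present in both the
  genome background file and the expression matrix;
* query lists are intersected with the universe before testing;
* hypergeometric upper tails for over-representation, two-sided Fisher
  exact tests for 2x2 contingency families, Benjamini-Hochberg
  correction within each analysis family.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSetDatabase, MasterGeneTable, RegulatorNetwork
from .stats import HypergeomQuery, bh_adjust, fisher_exact_two_sided, hypergeometric_tail

log = logging.getLogger("rnavista")


@dataclass
class EnrichmentResult:
    """One gene-set row of an over-representation analysis."""

    set_name: str
    overlap_genes: frozenset[str]
    k: int                  # overlap
    K: int                  # set size in universe
    n: int                  # query size
    N: int                  # universe size
    enrichment_ratio: float
    p: float
    adj_p: float = float("nan")


@dataclass
class RegulatorResult:
    """One regulator row of an upstream-regulator analysis."""

    regulator: str
    overlap_genes: frozenset[str]
    n_consistent: int
    n_inconsistent: int
    n_unknown: int
    activation_z: float
    k: int
    K: int
    n: int
    N: int
    p: float
    adj_p: float = float("nan")

    @property
    def state(self) -> str:
        if self.activation_z > 2:
            return "activated"
        if self.activation_z < -2:
            return "inhibited"
        return "enriched-only"


@dataclass
class SpatialResult:
    """Per-chromosome contingency tests for one comparison.

    ``tables`` maps family -> DataFrame indexed by chromosome with
    columns a, b, c, d (the 2x2 table), p and adj_p. Families:
    expression-bias, de-bias (among expressed genes) and direction-bias
    (among differential genes).
    """

    tables: dict[str, pd.DataFrame]


@dataclass
class OverlapResult:
    """Hypergeometric overlap statistics between two gene lists."""

    size_a: int
    size_b: int
    observed: int
    universe: int
    expected: float
    enrichment: float
    p: float
    overlap_genes: frozenset[str] = frozenset()


def build_universe(master: MasterGeneTable, background_symbols=None) -> set[str]:
    """Tested symbol universe: background ∩ expression-matrix genes.

    The master table already joins background annotation onto measured
    genes, so the universe is simply its non-empty symbols (upper-cased).
    """
    return set(master.symbols_for(master.gene_ids))


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def run_ora(query, db: GeneSetDatabase, universe,
            min_set: int = 3, max_set: int = 2000) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a query list in each gene set.

    Sets are restricted to the universe; sets with fewer than ``min_set``
    or more than ``max_set`` universe members are not tested. BH
    correction spans all tested sets; results are sorted by raw p
    ascending (ties by set name for determinism).
    """
    universe = {str(s).upper() for s in universe}
    query = {str(s).upper() for s in query} & universe
    N = len(universe)
    n = len(query)
    if n == 0:
        log.warning("ORA query is empty after universe intersection")
        return []
    results: list[EnrichmentResult] = []
    for set_name in sorted(db.sets):
        members = db.sets[set_name] & universe
        K = len(members)
        if K < min_set or K > max_set:
            continue
        overlap = members & query
        k = len(overlap)
        p = hypergeometric_tail(HypergeomQuery(k=k, K=K, n=n, N=N))
        ratio = (k / n) / (K / N)
        results.append(EnrichmentResult(
            set_name=set_name, overlap_genes=frozenset(overlap),
            k=k, K=K, n=n, N=N, enrichment_ratio=ratio, p=p))
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.adj_p = float(q)
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def run_ora_directional(master: MasterGeneTable, comparison: str,
                        db: GeneSetDatabase, universe,
                        min_set: int = 3, max_set: int = 2000,
                        ) -> dict[str, list[EnrichmentResult]]:
    """ORA of all, up-only and down-only significant genes of a comparison."""
    out: dict[str, list[EnrichmentResult]] = {}
    for direction in ("all", "up", "down"):
        genes = master.significant_genes(comparison, direction)
        query = master.symbols_for(genes)
        out[direction] = run_ora(query, db, universe, min_set, max_set)
    return out


# ---------------------------------------------------------------------------
# upstream regulators
# ---------------------------------------------------------------------------

def run_ura(master: MasterGeneTable, comparison: str, net: RegulatorNetwork,
            universe, min_regulon: int = 3) -> list[RegulatorResult]:
    """Upstream-regulator analysis from a signed regulator network.

    Overlap significance: hypergeometric test of regulon ∩ significant
    genes against the universe, BH-corrected across regulators.
    Activation z-score: over significant targets with a signed mode, a
    target is consistent when (Activation and up) or (Repression and
    down), inconsistent for the opposite pairing; z = (consistent −
    inconsistent) / sqrt(consistent + inconsistent), 0 when no signed
    targets. Unknown-mode targets count in the overlap but not in z.
    z > 2 ⇒ activated; z < −2 ⇒ inhibited; otherwise enriched-only.
    """
    universe = {str(s).upper() for s in universe}
    N = len(universe)
    sig_up = {s for s in master.symbols_for(master.significant_genes(comparison, "up"))}
    sig_down = {s for s in master.symbols_for(master.significant_genes(comparison, "down"))}
    sig = (sig_up | sig_down) & universe
    n = len(sig)
    results: list[RegulatorResult] = []
    for regulator in sorted(net.regulons()):
        targets = net.regulons()[regulator]
        regulon = {t: m for t, m in targets.items() if t in universe}
        K = len(regulon)
        if K < min_regulon:
            continue
        overlap = set(regulon) & sig
        k = len(overlap)
        n_cons = n_incons = n_unknown = 0
        for t in sorted(overlap):
            mode = regulon[t]
            if mode == "Unknown":
                n_unknown += 1
            elif (mode == "Activation" and t in sig_up) or (
                    mode == "Repression" and t in sig_down):
                n_cons += 1
            else:
                n_incons += 1
        denom = n_cons + n_incons
        z = (n_cons - n_incons) / np.sqrt(denom) if denom > 0 else 0.0
        p = hypergeometric_tail(HypergeomQuery(k=k, K=K, n=n, N=N)) if n else 1.0
        results.append(RegulatorResult(
            regulator=regulator, overlap_genes=frozenset(overlap),
            n_consistent=n_cons, n_inconsistent=n_incons, n_unknown=n_unknown,
            activation_z=float(z), k=k, K=K, n=n, N=N, p=p))
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.adj_p = float(q)
    results.sort(key=lambda r: (r.p, r.regulator))
    return results


# ---------------------------------------------------------------------------
# spatial (per-chromosome) enrichment
# ---------------------------------------------------------------------------

def run_spatial(master: MasterGeneTable, comparison: str,
                expressed_threshold: float = 1.0) -> SpatialResult:
    """Per-chromosome bias tests for one comparison.

    Three Fisher-exact families, each BH-corrected across chromosomes:

    * expression-bias — expressed vs not, on vs off the chromosome,
      over all annotated genes ("expressed" = mean expression across all
      samples >= ``expressed_threshold``);
    * de-bias — differential vs not, on vs off, among expressed genes;
    * direction-bias — up vs down, on vs off, among differential genes.

    Genes without chromosome annotation are excluded from all families;
    chromosomes with zero genes are skipped.
    """
    df = master.data
    chrom = df["chromosome"].astype(str)
    has_chrom = chrom.str.strip() != ""
    expressed = df[[f"expr:{s}" for s in master.sample_ids]].mean(axis=1) >= expressed_threshold
    calls = master.calls(comparison)
    de = calls.isin(["up", "down"])
    up = calls == "up"

    chroms = sorted(chrom[has_chrom].unique())
    families = {
        "expression-bias": (has_chrom, expressed),
        "de-bias": (has_chrom & expressed, de),
        "direction-bias": (has_chrom & de, up),
    }
    tables: dict[str, pd.DataFrame] = {}
    for fam, (pop_mask, attr) in families.items():
        rows = []
        for c in chroms:
            on = pop_mask & (chrom == c)
            off = pop_mask & (chrom != c)
            if int(on.sum()) == 0:
                continue
            a = int((on & attr).sum())
            b = int((on & ~attr).sum())
            cc = int((off & attr).sum())
            d = int((off & ~attr).sum())
            if a + b + cc + d < 1:
                continue
            p = fisher_exact_two_sided(a, b, cc, d)
            rows.append((c, a, b, cc, d, p))
        tab = pd.DataFrame(rows, columns=["chromosome", "a", "b", "c", "d", "p"])
        tab = tab.set_index("chromosome")
        tab["adj_p"] = bh_adjust(tab["p"]) if len(tab) else []
        tables[fam] = tab
    return SpatialResult(tables=tables)


# ---------------------------------------------------------------------------
# overlap
# ---------------------------------------------------------------------------

def run_overlap(list_a, list_b, universe) -> OverlapResult:
    """Size, enrichment and hypergeometric significance of |A ∩ B|."""
    universe = {str(s).upper() for s in universe}
    A = {str(s).upper() for s in list_a} & universe
    B = {str(s).upper() for s in list_b} & universe
    N = len(universe)
    inter = A & B
    expected = len(A) * len(B) / N if N else 0.0
    enrichment = len(inter) / expected if expected > 0 else 0.0
    p = hypergeometric_tail(HypergeomQuery(k=len(inter), K=len(A), n=len(B), N=N)) \
        if N else 1.0
    return OverlapResult(size_a=len(A), size_b=len(B), observed=len(inter),
                         universe=N, expected=expected, enrichment=enrichment,
                         p=p, overlap_genes=frozenset(inter))


# ---------------------------------------------------------------------------
# shared-genes network
# ---------------------------------------------------------------------------

def build_shared_gene_network(results, adj_p_cut: float = 0.05) -> nx.Graph:
    """Network of significant sets/regulators sharing > 50% of their genes.

    Nodes are results with adj_p < ``adj_p_cut``; node attributes: size
    (overlap-gene count) and intensity (−log10 p). An undirected edge
    joins two nodes when the shared fraction — |shared| divided by the
    smaller node's overlap-gene count — exceeds 0.5.
    """
    sig = [r for r in results if r.adj_p < adj_p_cut]
    G = nx.Graph()
    for r in sig:
        name = getattr(r, "set_name", None) or getattr(r, "regulator")
        G.add_node(name, size=len(r.overlap_genes),
                   intensity=float(-np.log10(max(r.p, 1e-300))),
                   genes=frozenset(r.overlap_genes))
    names = list(G.nodes)
    for i, u in enumerate(names):
        for v in names[i + 1:]:
            gu, gv = G.nodes[u]["genes"], G.nodes[v]["genes"]
            denom = min(len(gu), len(gv))
            if denom and len(gu & gv) / denom > 0.5:
                G.add_edge(u, v)
    return G


# ---------------------------------------------------------------------------
# tabular serialization (consumed by the workflow layer and users)
# ---------------------------------------------------------------------------

def ora_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set_name": r.set_name, "overlap": r.k, "set_size": r.K,
        "query_size": r.n, "universe": r.N,
        "enrichment_ratio": r.enrichment_ratio, "p": r.p, "adj_p": r.adj_p,
        "overlap_genes": ";".join(sorted(r.overlap_genes)),
    } for r in results])


def ura_to_frame(results: list[RegulatorResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "regulator": r.regulator, "overlap": r.k, "regulon_size": r.K,
        "n_significant": r.n, "universe": r.N,
        "n_consistent": r.n_consistent, "n_inconsistent": r.n_inconsistent,
        "n_unknown": r.n_unknown, "activation_z": r.activation_z,
        "state": r.state, "p": r.p, "adj_p": r.adj_p,
        "overlap_genes": ";".join(sorted(r.overlap_genes)),
    } for r in results])
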