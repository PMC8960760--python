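"""Driver-mutation nomination.

A triaged mutation is nominated as a potential driver when either of two
independent lines of evidence supports it: a "gold" pathogenicity medal
supplied as an input annotation (from an external classifier run upstream),
or significant clustering of the mutation within previously reported
somatic mutations.

The cluster test asks whether the background somatic mutations of a gene
pile up around the candidate's amino-acid position more than a uniform
scatter over the coding sequence would allow.  With ``N_g`` background
mutations in a gene of ``L_g`` codons, the count ``x`` of background
mutations within +-W residues of the candidate is compared to
``Binomial(N_g, pi)`` with window probability ``pi = min(1, (2W+1)/L_g)``;
the p-value is the exact upper tail ``P(X >= x)``.  Candidates are
corrected across the batch with Benjamini-Hochberg and called significant
at q < 0.05.  The candidate's own occurrence is never counted in ``x``:
the catalogue is external background, so a singleton novel variant cannot
inflate its own evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .cohort import VariantCall

DEFAULT_WINDOW = 5          # +-W amino acids
DEFAULT_FDR = 0.05


@dataclass
class GeneBackground:
    """Published somatic mutations for one gene: coding length in amino
    acids and (protein_pos, count) pairs."""

    gene: str
    length_aa: int
    positions: tuple = ()            # (protein_pos, count) pairs

    def __post_init__(self):
        if self.length_aa < 1:
            raise ValueError(f"{self.gene}: coding length must be >=1")
        for pos, count in self.positions:
            if not (1 <= pos <= self.length_aa):
                raise ValueError(f"{self.gene}: background position {pos} outside [1, {self.length_aa}]")
            if count < 1:
                raise ValueError(f"{self.gene}: background count {count} < 1")

    @property
    def total(self) -> int:
        return sum(c for _, c in self.positions)


class BackgroundCatalogue:
    """Per-gene background somatic-mutation catalogue."""

    def __init__(self, genes: Iterable[GeneBackground] = ()):
        self._genes = {g.gene: g for g in genes}

    def __contains__(self, gene: str) -> bool:
        return gene in self._genes

    def __getitem__(self, gene: str) -> GeneBackground:
        return self._genes[gene]

    def genes(self) -> list[str]:
        return sorted(self._genes)

    @classmethod
    def from_tsv(cls, path: str) -> "BackgroundCatalogue":
        """Read a (gene, length_aa, protein_pos, count) TSV."""
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        need = {"gene", "length_aa", "protein_pos", "count"}
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"catalogue TSV missing column(s): {', '.join(sorted(missing))}")
        genes = []
        for gene, grp in df.groupby("gene", sort=True):
            genes.append(GeneBackground(
                gene=str(gene), length_aa=int(grp["length_aa"].iloc[0]),
                positions=tuple((int(p), int(c))
                                for p, c in zip(grp["protein_pos"], grp["count"]))))
        return cls(genes)

    def to_tsv(self, path: str) -> None:
        import pandas as pd
        rows = [
            {"gene": g.gene, "length_aa": g.length_aa, "protein_pos": p, "count": c}
            for g in self._genes.values() for p, c in g.positions
        ]
        pd.DataFrame(rows, columns=["gene", "length_aa", "protein_pos", "count"]) \
            .to_csv(path, sep="\t", index=False)


@dataclass
class ClusterTestResult:
    gene: str
    protein_pos: int
    window: int
    x: int                               # in-window background count
    n_background: int
    window_prob: float
    p_value: Optional[float]
    q_value: Optional[float] = None
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.q_value is not None and self.q_value < DEFAULT_FDR


def cluster_test(gene: str, protein_pos: int,
                 catalogue: BackgroundCatalogue,
                 window: int = DEFAULT_WINDOW) -> ClusterTestResult:
    """Exact binomial window-enrichment test at one candidate position.

    Returns p undefined (flagged "no background") when the gene is absent
    from the catalogue.  An empty per-gene background gives x=0, p=1.
    """
    if gene not in catalogue:
        return ClusterTestResult(gene, protein_pos, window, 0, 0, 0.0,
                                 None, note="no background")
    bg = catalogue[gene]
    pi = min(1.0, (2 * window + 1) / bg.length_aa)
    x = sum(c for pos, c in bg.positions if abs(pos - protein_pos) <= window)
    n = bg.total
    if n == 0:
        return ClusterTestResult(gene, protein_pos, window, 0, 0, pi, 1.0)
    # exact upper tail P(X >= x); sf(x-1) = P(X > x-1)
    p = float(binom.sf(x - 1, n, pi)) if x > 0 else 1.0
    return ClusterTestResult(gene, protein_pos, window, x, n, pi, min(p, 1.0))


def fdr_adjust(results: Sequence[ClusterTestResult]) -> list[ClusterTestResult]:
    """Benjamini-Hochberg step-up across the candidate batch (in place).

    Results with undefined p (no background) are passed through with
    q=None and do not count toward the batch size m.
    """
    defined = [r for r in results if r.p_value is not None]
    if defined:
        q = multipletests([r.p_value for r in defined], method="fdr_bh")[1]
        for r, qv in zip(defined, q):
            r.q_value = float(qv)
    return list(results)


def cluster_test_batch(candidates: Sequence[tuple],
                       catalogue: BackgroundCatalogue,
                       window: int = DEFAULT_WINDOW) -> list[ClusterTestResult]:
    """Run the cluster test over (gene, protein_pos) candidates and BH-adjust."""
    return fdr_adjust([cluster_test(g, p, catalogue, window) for g, p in candidates])


@dataclass
class Nomination:
    variant: VariantCall
    is_driver: bool
    justification: tuple = ()            # subset of ("gold_medal", "cluster")
    medal: str = "none"
    q_value: Optional[float] = None


def nominate(variants: Sequence[VariantCall],
             medals: Sequence[str],
             cluster_results: Sequence[Optional[ClusterTestResult]],
             fdr: float = DEFAULT_FDR) -> list[Nomination]:
    """Driver iff medal == gold OR cluster q < fdr; keeps the justification.

    ``medals`` and ``cluster_results`` align positionally with
    ``variants``; a missing cluster result (no protein position or no
    background) is None.
    """
    if not (len(variants) == len(medals) == len(cluster_results)):
        raise ValueError("variants, medals and cluster_results must align")
    out = []
    for v, medal, cr in zip(variants, medals, cluster_results):
        just = []
        if medal == "gold":
            just.append("gold_medal")
        q = cr.q_value if cr is not None else None
        if q is not None and q < fdr:
            just.append("cluster")
        out.append(Nomination(v, bool(just), tuple(just), medal, q))
    return out


def nominated_drivers(nominations: Iterable[Nomination]) -> list[VariantCall]:
    return [n.variant for n in nominations if n.is_driver]
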