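"""From miRNA fold changes to gene-level functional predictions.

Three steps: (1) a consensus target map keeping miRNA->gene edges predicted
by at least 2 of 3 databases; (2) the Hill/logistic binding argument, under
which a fold change FC in free miRNA multiplies the bound-fraction odds
theta/(1-theta) = L/K_d by FC, so the log-odds ratio between states is
ln(FC); (3) DerSimonian-Laird random-effects pooling of the Delta-Delta-Cq
posteriors of all miRNAs targeting a gene, giving a per-gene direction call
(miRNAs up => target mRNA predicted down, and vice versa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import TargetDB

LN2 = math.log(2.0)


@dataclass
class ConsensusMap:
    """miRNA -> gene sets where each edge has >= ``min_db`` database support."""

    targets: dict[str, set[str]] = field(default_factory=dict)
    min_db: int = 2

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.targets.values():
            out |= s
        return out

    def mirnas_targeting(self, gene: str) -> list[str]:
        return sorted(m for m, gs in self.targets.items() if gene in gs)


def consensus_targets(dbs: list[TargetDB], min_db: int = 2) -> ConsensusMap:
    """Keep edges supported by at least ``min_db`` of the given databases."""
    if min_db > len(dbs):
        raise ValueError(f"min_db={min_db} exceeds the {len(dbs)} databases given")
    if min_db < 1:
        raise ValueError("min_db must be >= 1")
    support: dict[tuple[str, str], int] = {}
    for db in dbs:
        for edge in db.edges:
            support[edge] = support.get(edge, 0) + 1
    targets: dict[str, set[str]] = {}
    for (m, g), n in support.items():
        if n >= min_db:
            targets.setdefault(m, set()).add(g)
    return ConsensusMap(targets=targets, min_db=min_db)


def hill_log_odds(fc, hill_coefficient: float = 1.0):
    """Natural-log odds ratio of the bound fraction implied by a fold change.

    With theta = L/(L+K_d) the odds are theta/(1-theta) = L/K_d, so a change
    L_R -> L_E multiplies the odds by FC = L_E/L_R and the log-odds ratio is
    ln(FC); K_d cancels.  A Hill cooperativity coefficient n scales the
    log-odds by n (default 1, plain logistic binding).
    """
    arr = np.asarray(fc, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("fold change must be positive")
    out = hill_coefficient * np.log(arr)
    return float(out) if np.isscalar(fc) or arr.ndim == 0 else out


@dataclass
class GeneProfile:
    """Pooled Delta-Delta-Cq evidence over all miRNAs targeting one gene."""

    gene_id: str
    k_studies: int
    pooled_ddcq: float
    pooled_se: float
    tau2: float
    z: float
    p: float
    log_odds: float       # ln(2^-pooled_ddcq), the pooled bound-fraction log-odds
    direction: str        # mRNA_up | mRNA_down | indeterminate
    mirnas: list[str] = field(default_factory=list)


def dersimonian_laird(effects, ses) -> tuple[float, float, float]:
    """DerSimonian-Laird random-effects pooling.

    Returns ``(pooled, pooled_se, tau2)``.  Fixed weights w_i = 1/se_i^2 give
    Q = sum w_i (y_i - ybar_w)^2 and the moment estimator
    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); random weights
    1/(se_i^2 + tau^2) then produce the pooled mean and its SE.
    """
    y = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    if y.shape != se.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("effects and ses must be equal-length 1-D arrays")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    k = len(y)
    if k == 1:
        return float(y[0]), float(se[0]), 0.0
    w = 1.0 / se**2
    ybar = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - ybar) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    wstar = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(wstar * y) / np.sum(wstar))
    pooled_se = float(np.sum(wstar) ** -0.5)
    return pooled, pooled_se, tau2


def gene_meta_analysis(summaries, cmap: ConsensusMap, gene: str, alpha: float = 0.05) -> GeneProfile:
    """Pool the Delta-Delta-Cq posteriors of all miRNAs targeting ``gene``.

    ``summaries`` maps species_id -> an object with ``ddcq_mean`` and
    ``ddcq_se`` attributes (or a (mean, se) tuple).  Posterior means and SEs
    are pooled on the Cq scale; the pooled value is reported also as a
    bound-fraction log-odds via ln(2^-pooled).
    """
    mirnas = [m for m in cmap.mirnas_targeting(gene) if m in summaries]
    if not mirnas:
        raise ValueError(f"gene {gene!r} has no targeting miRNA with a posterior summary")
    eff, ses = [], []
    for m in mirnas:
        s = summaries[m]
        if hasattr(s, "ddcq_mean"):
            eff.append(s.ddcq_mean)
            ses.append(s.ddcq_se)
        else:
            eff.append(s[0])
            ses.append(s[1])
    pooled, pooled_se, tau2 = dersimonian_laird(eff, ses)
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    if p <= alpha:
        direction = "mRNA_down" if pooled < 0 else "mRNA_up"
    else:
        direction = "indeterminate"
    return GeneProfile(
        gene_id=gene,
        k_studies=len(mirnas),
        pooled_ddcq=pooled,
        pooled_se=pooled_se,
        tau2=tau2,
        z=z,
        p=p,
        log_odds=-pooled * LN2,
        direction=direction,
        mirnas=mirnas,
    )


def profile_genes(summaries, cmap: ConsensusMap, alpha: float = 0.05) -> list[GeneProfile]:
    """Gene profiles for every gene in the consensus map with usable evidence."""
    out = []
    for gene in sorted(cmap.genes()):
        if any(m in summaries for m in cmap.mirnas_targeting(gene)):
            out.append(gene_meta_analysis(summaries, cmap, gene, alpha=alpha))
    return out


def functional_profile(profiles: list[GeneProfile], alpha: float = 0.05) -> tuple[set[str], set[str]]:
    """Split genes into predicted-up and predicted-down sets at level ``alpha``.

    A gene is called mRNA_down when its targeting miRNAs are pooled up
    (pooled Delta-Delta-Cq < 0, i.e. higher miRNA concentration) at p <= alpha,
    and mRNA_up in the mirror case.
    """
    genes_up = {g.gene_id for g in profiles if g.p <= alpha and g.pooled_ddcq > 0}
    genes_down = {g.gene_id for g in profiles if g.p <= alpha and g.pooled_ddcq < 0}
    return genes_up, genes_down
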