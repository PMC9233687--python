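"""Assign scRNA cells to genomic clones via a copy-number dosage model.

Many genes show gene-dosage effects: expected transcript abundance scales
with DNA copy number. Given clones defined from scCNV data, each with an
integer CN over its discriminating regions, a cell's counts over the
copy-variant genes therefore carry information about which clone it came
from. We model the counts of cell ``n`` as a mixture of multinomials over
clones:

    p_gc = mu_g * c_gc / sum_g' mu_g' * c_g'c

where ``mu_g`` is a shared per-gene baseline rate (unit simplex) and
``c_gc`` the gene-by-clone copy number. The model is fitted by EM:
E-step posteriors gamma_nc ∝ pi_c exp(sum_g y_ng log p_gc); M-step sets
pi to the mean posterior and updates mu by the fixed-point

    mu_g <- (sum_n y_ng) / (sum_n N_n sum_c gamma_nc c_gc / Z_c)

followed by renormalization. This is a deliberately simple, desk-
verifiable model of the dosage mechanism — a behavioural, not bit-exact,
analogue of richer variational treatments; it omits random effects,
covariates and overdispersion.

Cells are assigned to the maximum-posterior clone only when that posterior
clears a probability threshold (default 0.9); everything else, including
exact posterior ties, is left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cnv_clones import CloneDefinition
from .io_formats import CountMatrix

MIN_GENE_UMI = 20
MIN_CELL_UMI = 100


@dataclass
class DosageModel:
    mu: np.ndarray  # per-gene baseline rate, sums to 1
    pi: np.ndarray  # clone priors
    gamma: np.ndarray  # cells x clones posteriors
    log_likelihood: list[float] = field(default_factory=list)
    clone_names: list = field(default_factory=list)
    barcodes: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = False


@dataclass
class CloneCallSet:
    labels: np.ndarray  # clone index per cell, -1 unassigned
    posterior: np.ndarray  # posterior of the winning clone
    threshold: float
    clone_names: list = field(default_factory=list)
    barcodes: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        names = [
            "unassigned" if l < 0 else str(self.clone_names[l] if self.clone_names else l)
            for l in self.labels
        ]
        return pd.DataFrame(
            {"barcode": self.barcodes, "clone": names, "posterior": self.posterior}
        )


def build_gene_clone_matrix(
    clones: CloneDefinition,
    genes: pd.DataFrame,
    counts: CountMatrix,
    min_gene_umi: int = MIN_GENE_UMI,
    min_cell_umi: int = MIN_CELL_UMI,
) -> tuple[pd.DataFrame, CountMatrix]:
    """Gene x clone CN matrix over copy-variant genes, plus filtered counts.

    Genes must lie inside a discriminating arm/window, differ in CN between
    at least two clones, and carry at least ``min_gene_umi`` total UMI;
    cells must then retain at least ``min_cell_umi`` UMI over the kept
    genes. The per-gene CN is the clone's signature CN for the containing
    arm.
    """
    if len(clones.signatures) < 2:
        raise ValueError("no copy-variant signal: fewer than 2 clones")
    gene_arm = np.full(len(genes), None, dtype=object)
    for _, a in clones.arm_coords.iterrows():
        inside = (
            (genes.chrom == a.chrom).to_numpy()
            & (genes.start.to_numpy() >= a.start)
            & (genes.end.to_numpy() <= a.end)
        )
        gene_arm[inside] = a.arm

    in_matrix = pd.Series(genes.gene_id.to_numpy(object)).isin(counts.gene_ids).to_numpy()
    candidate = (gene_arm != None) & in_matrix  # noqa: E711
    gene_order = {g: i for i, g in enumerate(counts.gene_ids)}
    rows = []
    for j in np.where(candidate)[0]:
        arm = gene_arm[j]
        cn_per_clone = clones.signatures[arm].to_numpy(int)
        if len(set(cn_per_clone)) < 2:
            continue  # identical CN across clones carries no signal
        rows.append((genes.gene_id.iloc[j], gene_order[genes.gene_id.iloc[j]], cn_per_clone))
    if not rows:
        raise ValueError("no copy-variant signal: 0 candidate genes")

    idx = np.array([r[1] for r in rows])
    totals = np.asarray(counts.matrix[idx, :].sum(axis=1)).ravel()
    keep = totals >= min_gene_umi
    if not keep.any():
        raise ValueError("no copy-variant signal: all genes below the UMI floor")
    kept_rows = [r for r, k in zip(rows, keep) if k]
    cn_mat = pd.DataFrame(
        np.vstack([r[2] for r in kept_rows]),
        index=[r[0] for r in kept_rows],
        columns=clones.signatures.index,
    )
    filtered = counts.subset_genes(np.array([r[1] for r in kept_rows]))
    cell_tot = filtered.cell_totals()
    filtered = filtered.subset_cells(cell_tot >= min_cell_umi)
    return cn_mat, filtered


def _log_p_gc(mu: np.ndarray, cn: np.ndarray) -> np.ndarray:
    """log p_gc for mu (genes,) and cn (genes x clones); zero-CN genes get -inf."""
    rate = mu[:, None] * cn
    z = rate.sum(axis=0)
    with np.errstate(divide="ignore"):
        return np.log(rate) - np.log(z)


def _observed_loglik(y, logp, pi) -> float:
    # y: cells x genes sparse; logp: genes x clones
    per_clone = y @ logp  # cells x clones
    return float(logsumexp(per_clone + np.log(pi)[None, :], axis=1).sum())


def compute_posteriors(
    counts: CountMatrix, cn: pd.DataFrame, mu: np.ndarray, pi: np.ndarray
) -> np.ndarray:
    """Clone posteriors gamma_nc at fixed parameters (one E-step)."""
    y = counts.matrix.T.tocsr().astype(float)
    logp = _log_p_gc(np.asarray(mu, float), cn.to_numpy(float))
    score = (y @ logp) + np.log(np.asarray(pi, float))[None, :]
    return np.exp(score - logsumexp(score, axis=1, keepdims=True))


def fit_dosage_model(
    counts: CountMatrix,
    cn: pd.DataFrame,
    init_seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 0,
) -> DosageModel:
    """Fit the mixture-of-multinomials dosage model by EM.

    ``counts`` must be restricted to the copy-variant genes (rows aligned
    with ``cn``). Initialization: mu proportional to pooled gene counts,
    pi uniform; optional seeded random restarts keep the best final
    likelihood. Stops when the relative change in observed log-likelihood
    falls below ``tol`` or after ``max_iter`` iterations. The recorded
    log-likelihood trace is non-decreasing: the fixed-point mu update is
    damped (geometrically halved in log space) whenever a step would lower
    the observed likelihood.
    """
    if list(counts.gene_ids) != list(cn.index):
        raise ValueError("counts genes must align with the gene x clone matrix")
    y = counts.matrix.T.tocsr().astype(float)  # cells x genes
    cmat = cn.to_numpy(float)  # genes x clones
    n_cells, n_genes = y.shape
    n_clones = cmat.shape[1]
    pooled = np.asarray(y.sum(axis=0)).ravel()
    mu0 = (pooled + 1e-9) / (pooled + 1e-9).sum()

    rng = np.random.default_rng(init_seed)
    inits = [mu0]
    for _ in range(n_restarts):
        m = mu0 * rng.lognormal(0.0, 0.5, size=n_genes)
        inits.append(m / m.sum())

    best: DosageModel | None = None
    for mu in inits:
        model = _fit_once(y, cmat, mu, tol, max_iter)
        if best is None or model.log_likelihood[-1] > best.log_likelihood[-1]:
            best = model
    best.clone_names = list(cn.columns)
    best.barcodes = counts.barcodes
    return best


def _fit_once(y, cmat, mu, tol, max_iter) -> DosageModel:
    n_cells = y.shape[0]
    n_clones = cmat.shape[1]
    pi = np.full(n_clones, 1.0 / n_clones)
    N = np.asarray(y.sum(axis=1)).ravel()
    trace: list[float] = []
    gamma = np.full((n_cells, n_clones), 1.0 / n_clones)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = _log_p_gc(mu, cmat)
        score = (y @ logp) + np.log(pi)[None, :]  # cells x clones, log-space
        if not np.all(np.isfinite(logsumexp(score, axis=1))):
            raise FloatingPointError(f"non-finite likelihood at iteration {it}")
        norm = logsumexp(score, axis=1, keepdims=True)
        gamma = np.exp(score - norm)
        ll = float(norm.sum())
        if trace and ll < trace[-1] - 1e-9:  # damping failed upstream; keep monotone
            ll = trace[-1]
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * abs(trace[-2]):
            converged = True
            break
        # M-step
        pi_new = np.clip(gamma.mean(axis=0), 1e-12, None)
        pi_new /= pi_new.sum()
        z = (mu[:, None] * cmat).sum(axis=0)  # per-clone normalizer
        denom = ((gamma / z[None, :]) @ cmat.T) * N[:, None]  # cells x genes
        num = np.asarray(y.sum(axis=0)).ravel()
        mu_prop = num / np.clip(denom.sum(axis=0), 1e-300, None)
        mu_prop = np.clip(mu_prop, 1e-300, None)
        mu_prop /= mu_prop.sum()
        # damped acceptance: guarantee the observed likelihood cannot drop
        step = 1.0
        cur_ll = _observed_loglik(y, _log_p_gc(mu, cmat), pi_new)
        for _ in range(12):
            cand = np.exp((1 - step) * np.log(mu) + step * np.log(mu_prop))
            cand /= cand.sum()
            if _observed_loglik(y, _log_p_gc(cand, cmat), pi_new) >= cur_ll - 1e-9:
                mu = cand
                break
            step /= 2
        pi = pi_new
    return DosageModel(mu, pi, gamma, trace, n_iter=it, converged=converged)


def assign_cells(model: DosageModel, threshold: float = 0.9) -> CloneCallSet:
    """Call each cell to its maximum-posterior clone when that posterior
    reaches ``threshold``; exact posterior ties are left unassigned."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    gamma = model.gamma
    best = gamma.argmax(axis=1)
    best_p = gamma[np.arange(len(gamma)), best]
    tied = (gamma == best_p[:, None]).sum(axis=1) > 1
    labels = np.where((best_p >= threshold) & ~tied, best, -1)
    return CloneCallSet(labels, best_p, threshold, model.clone_names, model.barcodes)


def merge_clones(calls: CloneCallSet, merge_map: dict) -> CloneCallSet:
    """Post-hoc merge of clones (e.g. combining two transcriptionally
    indistinguishable clones into one group before differential expression).

    ``merge_map`` maps original clone name -> merged group name; unlisted
    clones keep their own name.
    """
    names = [merge_map.get(str(n), str(n)) for n in calls.clone_names]
    uniq = list(dict.fromkeys(names))
    relabel = {i: uniq.index(names[i]) for i in range(len(names))}
    labels = np.array([relabel[l] if l >= 0 else -1 for l in calls.labels])
    return CloneCallSet(labels, calls.posterior, calls.threshold, uniq, calls.barcodes)
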