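"""Model-based genetic-ancestry estimation by supervised projection.

A labeled reference panel yields a K x M population allele-frequency matrix
F (one frequency per population per LD-pruned variant).  New samples are
projected onto that model by maximizing the binomial genotype likelihood

    l(q) = sum_m [ g_m log p_m + (2 - g_m) log(1 - p_m) ],   p_m = sum_k q_k f_km

over the simplex via expectation-maximization from a uniform start.  This
is the likelihood admixture-model tools maximize in projection mode; with
a labeled reference the per-population frequencies are estimable directly
(with a pseudocount), which removes label switching and makes the fit
deterministic.  An unsupervised mode alternating F and Q updates is
available for fidelity, initialized from the supervised fit.

PCA of the resulting Q vectors (rank at most K-1 on the simplex) gives the
standard two-dimensional summary of cohort ancestry composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, VariantKey

FREQ_CLAMP = 1e-4  # keeps log-likelihood finite at fixed reference alleles


@dataclass
class AncestryModel:
    F: np.ndarray                    # K x M counted-allele frequencies
    population_names: list[str]
    variant_keys: list[VariantKey]

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        K, M = self.F.shape
        if K != len(self.population_names):
            raise ValueError("one frequency row per population required")
        if M != len(self.variant_keys):
            raise ValueError("one frequency column per variant required")
        if ((self.F <= 0) | (self.F >= 1)).any():
            raise ValueError("model frequencies must lie strictly in (0,1)")

    @property
    def n_populations(self) -> int:
        return self.F.shape[0]


@dataclass
class AncestryProportions:
    sample_id: str
    Q: np.ndarray          # length-K simplex vector
    loglik: float
    n_iter: int
    converged: bool
    flag: str = ""         # "", "non_identifiable", "no_overlapping_calls"

    @property
    def defined(self) -> bool:
        return self.flag != "no_overlapping_calls"


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(matrix: GenotypeMatrix, window: int = 50, step: int = 10,
             r2_max: float = 0.1) -> list[VariantKey]:
    """Greedy sliding-window LD pruning on squared genotype correlation.

    Variants must be ordered by chromosome and position.  Within each
    window, any retained pair with r² above ``r2_max`` drops the later
    variant (by position; lower minor-allele frequency on ties); windows
    advance by ``step`` SNPs.  Monomorphic variants have undefined r² and
    are retained without entering the comparison.
    """
    if window < 2 or window < step:
        raise ValueError("require window >= 2 and window >= step")
    order = [(v.chromosome, v.position) for v in matrix.variants]
    if order != sorted(order, key=lambda t: (t[0].rjust(2, "0"), t[1])):
        raise ValueError("variants must be sorted by chromosome and position")
    g = matrix.calls.astype(float)
    g[matrix.calls == MISSING] = np.nan
    col_mean = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
    filled = np.where(np.isnan(g), col_mean, g)
    freqs = col_mean / 2.0
    maf = np.minimum(freqs, 1 - freqs)
    variance = filled.var(axis=0)
    m = matrix.n_variants
    keep = np.ones(m, dtype=bool)
    # chromosome boundaries: windows never span chromosomes
    chrom = np.array([v.chromosome for v in matrix.variants])
    for start in range(0, m, step):
        idx = np.arange(start, min(start + window, m))
        idx = idx[chrom[idx] == chrom[idx[0]]]
        idx = idx[keep[idx] & (variance[idx] > 0)]
        if len(idx) < 2:
            continue
        block = filled[:, idx]
        r = np.corrcoef(block, rowvar=False)
        r2 = r ** 2
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if not keep[idx[b]]:
                    continue
                if r2[a, b] > r2_max:
                    va, vb = matrix.variants[idx[a]], matrix.variants[idx[b]]
                    if va.position == vb.position and maf[idx[b]] > maf[idx[a]]:
                        keep[idx[a]] = False
                        break
                    keep[idx[b]] = False
        if not keep[idx].any():
            continue
    return [v for v, k in zip(matrix.variants, keep) if k]


# ---------------------------------------------------------------------------
# supervised model fit
# ---------------------------------------------------------------------------

def fit_reference(matrix: GenotypeMatrix, population_labels: dict[str, str],
                  pseudocount: float = 0.5) -> AncestryModel:
    """Per-population counted-allele frequencies with a pseudocount.

    f_km = (allele count + pc) / (2 n_called + 2 pc), clamped to (0,1);
    an all-missing variant in a population falls back to 0.5.
    """
    missing = [s for s in matrix.sample_ids if s not in population_labels]
    if missing:
        raise ValueError(f"population label missing for samples: {missing[:5]}")
    pops = sorted(set(population_labels[s] for s in matrix.sample_ids))
    K, M = len(pops), matrix.n_variants
    F = np.empty((K, M))
    for k, pop in enumerate(pops):
        rows = [i for i, s in enumerate(matrix.sample_ids)
                if population_labels[s] == pop]
        calls = matrix.calls[rows]
        valid = calls != MISSING
        alt = np.where(valid, calls, 0).sum(axis=0)
        n_called = valid.sum(axis=0)
        F[k] = (alt + pseudocount) / (2 * n_called + 2 * pseudocount)
    F = np.clip(F, FREQ_CLAMP, 1 - FREQ_CLAMP)
    return AncestryModel(F, pops, list(matrix.variants))


# ---------------------------------------------------------------------------
# projection (EM on the simplex)
# ---------------------------------------------------------------------------

def _loglik(G: np.ndarray, mask: np.ndarray, Q: np.ndarray, F: np.ndarray
            ) -> np.ndarray:
    P = np.clip(Q @ F, FREQ_CLAMP / 2, 1 - FREQ_CLAMP / 2)
    ll = np.where(mask, G * np.log(P) + (2 - G) * np.log1p(-P), 0.0)
    return ll.sum(axis=1)


def project(matrix: GenotypeMatrix, model: AncestryModel, tol: float = 1e-6,
            max_iter: int = 1000) -> list[AncestryProportions]:
    """Maximum-likelihood ancestry proportions for each sample.

    Expectation-maximization from a uniform start; converged when the
    largest per-sample change in Q drops below ``tol``.  Missing genotypes
    are skipped.  Samples with no overlapping non-missing calls, and models
    whose population frequencies are identical everywhere (flat likelihood),
    are flagged rather than silently returned.
    """
    keys_model = [(v.chromosome, v.position) for v in model.variant_keys]
    keys_mat = [(v.chromosome, v.position) for v in matrix.variants]
    if keys_mat != keys_model:
        raise ValueError("matrix must be restricted/harmonized to model variants")
    F = model.F
    K, M = F.shape
    n = matrix.n_samples
    G = matrix.calls.astype(float)
    mask = matrix.calls != MISSING
    G[~mask] = 0.0
    non_identifiable = bool(np.allclose(F, F[0:1], atol=1e-12))
    Q = np.full((n, K), 1.0 / K)
    n_valid = mask.sum(axis=1).astype(float)
    active = n_valid > 0
    iters = np.zeros(n, dtype=int)
    converged = np.zeros(n, dtype=bool)
    live = active & ~converged
    for it in range(1, max_iter + 1):
        if not live.any() or non_identifiable:
            break
        Qa = Q[live]
        Ga, maska = G[live], mask[live]
        P = np.clip(Qa @ F, FREQ_CLAMP / 2, 1 - FREQ_CLAMP / 2)   # n' x M
        # allele-level responsibilities, summed over variants
        A = (Ga / P) @ F.T * Qa                   # counted-allele copies
        B = ((2 - Ga) * maska / (1 - P)) @ (1 - F).T * Qa
        newQ = (A + B) / (2 * n_valid[live])[:, None]
        newQ /= newQ.sum(axis=1, keepdims=True)
        delta = np.abs(newQ - Qa).max(axis=1)
        Q[live] = newQ
        iters[live] = it
        done = delta < tol
        live_idx = np.flatnonzero(live)
        converged[live_idx[done]] = True
        live = active & ~converged
    ll = _loglik(G, mask, Q, F)
    out = []
    for i, sid in enumerate(matrix.sample_ids):
        flag = ""
        if not active[i]:
            flag = "no_overlapping_calls"
        elif non_identifiable:
            flag = "non_identifiable"
        out.append(AncestryProportions(
            sid, Q[i].copy(), float(ll[i]), int(iters[i]),
            bool(converged[i] or non_identifiable), flag))
    return out


# ---------------------------------------------------------------------------
# unsupervised refinement (optional fidelity mode)
# ---------------------------------------------------------------------------

def fit_unsupervised(matrix: GenotypeMatrix, model: AncestryModel,
                     n_outer: int = 20, tol: float = 1e-5,
                     max_iter: int = 200) -> tuple[AncestryModel, list[AncestryProportions]]:
    """Alternate F and Q EM updates, initialized from a supervised fit."""
    F = model.F.copy()
    G = matrix.calls.astype(float)
    mask = matrix.calls != MISSING
    G[~mask] = 0.0
    current = model
    props = project(matrix, current, tol=tol, max_iter=max_iter)
    for _ in range(n_outer):
        Q = np.vstack([p.Q for p in props])
        P = np.clip(Q @ F, FREQ_CLAMP / 2, 1 - FREQ_CLAMP / 2)
        # expected counted-allele copies attributed to population k
        num = ((G / P).T @ Q) * F.T                    # M x K
        den = num + (((2 - G) * mask / (1 - P)).T @ Q) * (1 - F).T
        F = np.clip((num / np.maximum(den, 1e-12)).T, FREQ_CLAMP, 1 - FREQ_CLAMP)
        current = AncestryModel(F, model.population_names, model.variant_keys)
        props = project(matrix, current, tol=tol, max_iter=max_iter)
    return current, props


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def pca_of_Q(Q_matrix: np.ndarray, n_components: int = 2
             ) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of the n x K proportion matrix with a fixed sign rule.

    Each component's largest-magnitude loading is made positive so repeated
    runs produce identical coordinates.  Returns (coordinates, explained
    variance ratio); degenerate (zero-variance) input gives all-zero
    coordinates.
    """
    from sklearn.decomposition import PCA

    Q = np.asarray(Q_matrix, dtype=float)
    n_components = min(n_components, *Q.shape)
    centered = Q - Q.mean(axis=0)
    if np.allclose(centered, 0):
        return np.zeros((Q.shape[0], n_components)), np.zeros(n_components)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(Q)
    for c in range(coords.shape[1]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] = -coords[:, c]
    total = pca.explained_variance_.sum()
    evr = pca.explained_variance_ratio_ if total > 0 else np.zeros(n_components)
    return coords, evr


def assign_majority_ancestry(props: list[AncestryProportions],
                             population_names: list[str]
                             ) -> list[tuple[str, str, bool]]:
    """(sample_id, majority population, tie flag); flagged samples unassigned."""
    out = []
    for p in props:
        if not p.defined:
            out.append((p.sample_id, "unassigned", False))
            continue
        best = float(np.max(p.Q))
        winners = np.flatnonzero(np.isclose(p.Q, best, rtol=0, atol=1e-12))
        out.append((p.sample_id, population_names[int(winners[0])],
                    len(winners) > 1))
    return out
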