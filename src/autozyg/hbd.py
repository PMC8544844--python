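"""Multi-class homozygosity-by-descent (HBD) hidden Markov mixture model.

The genome of an individual is modelled as a mosaic of segments, each
belonging to one of several HBD age classes or to a non-HBD class.  Segment
lengths are exponential with a class-specific rate ``R_K`` (in 1/Morgan):
a class of rate R has expected segment length 1/R Morgan and corresponds to
common ancestors living about R/2 generations ago, so high rates capture
ancient, short HBD stretches and low rates recent, long ones.  In the MixKR
variant the rates are fixed a priori (here 2^1..2^6 for six HBD classes,
with the non-HBD class fixed at the most ancient rate) and only the mixing
coefficients — the probability that a new segment belongs to each class —
are estimated, per individual, by expectation-maximization.

Emission model at a marker with allele-1 frequency ``f`` and genotyping
error ``eps``: a non-HBD locus emits Hardy-Weinberg genotype probabilities
``(f^2, 2f(1-f), (1-f)^2)``; an HBD locus copies a single allele, emitting
``(1-eps) * (f, 0, 1-f) + eps * HW``.  Missing genotypes are uninformative
(emission 1 in every class).  Between adjacent markers separated by ``d``
Morgans the chain either stays in its segment, with probability
``exp(-R_c d)``, or starts a new segment whose class is drawn from the
mixing vector.  Chromosomes are independent chains initialized at the
mixing distribution.

Averaging the summed HBD-class posterior over all markers gives the
genome-wide inbreeding coefficient ``F_G``; restricting the sum to classes
with rate at most ``T`` gives ``F_G-T``, inbreeding relative to a base
population about ``T/2`` generations ago.

The statsmodels-style entry point is :class:`HBDMixtureModel` built from a
:class:`~autozyg.genotypes.GenotypeDataset`; its :meth:`~HBDMixtureModel.fit`
returns an :class:`HBDMixtureResults` carrying per-individual mixing
estimates, posteriors, F_G and a summary table.  The module-level functions
(:func:`forward_backward`, :func:`em_fit`, ...) expose the same machinery
for single individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, MORGANS_PER_BP, GenotypeDataset, allele_frequencies

DEFAULT_HBD_RATES = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
DEFAULT_NON_HBD_RATE = 64.0


@dataclass(frozen=True)
class HBDParameters:
    """MixKR parameterization: fixed class rates, per-individual mixing."""

    rates: tuple[float, ...] = DEFAULT_HBD_RATES
    non_hbd_rate: float = DEFAULT_NON_HBD_RATE
    mixing: np.ndarray | None = None  # length n_classes; None -> uniform
    epsilon: float = 0.001
    morgans_per_bp: float = MORGANS_PER_BP

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if np.any(rates <= 0) or self.non_hbd_rate <= 0:
            raise ValueError("rates must be strictly positive")
        if np.any(np.diff(rates) < 0):
            raise ValueError("HBD rates must be non-decreasing")
        if not (0 <= self.epsilon <= 0.1):
            raise ValueError("epsilon must lie in [0, 0.1]")
        if self.mixing is not None:
            mixing = np.asarray(self.mixing, dtype=float)
            if len(mixing) != self.n_classes:
                raise ValueError("mixing length must be n_hbd_classes + 1")
            if abs(mixing.sum() - 1.0) > 1e-9 or np.any(mixing < 0):
                raise ValueError("mixing must be a probability vector")

    @property
    def n_classes(self) -> int:
        return len(self.rates) + 1

    @property
    def all_rates(self) -> np.ndarray:
        """Rates of every class; the non-HBD class is last."""
        return np.append(np.asarray(self.rates, dtype=float), self.non_hbd_rate)

    @property
    def mixing_or_uniform(self) -> np.ndarray:
        if self.mixing is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.mixing, dtype=float)


@dataclass
class HBDPosterior:
    """Per-marker posterior over the HBD classes + non-HBD (last column)."""

    probs: np.ndarray  # n_markers x n_classes, rows sum to 1
    log_likelihood: float
    rates: np.ndarray  # all class rates, non-HBD last

    @property
    def class_means(self) -> np.ndarray:
        """Genome-averaged posterior probability of each class."""
        return self.probs.mean(axis=0)

    @property
    def hbd_mass(self) -> np.ndarray:
        """Per-marker total HBD probability (all classes but the last)."""
        return self.probs[:, :-1].sum(axis=1)


def generations_from_rate(rate: float) -> float:
    """Number of generations to the common ancestor of a class: R/2."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return rate / 2.0


def expected_segment_length_mbp(
    rate: float, morgans_per_bp: float = MORGANS_PER_BP
) -> float:
    """Expected HBD segment length of a class, 1/R Morgan, in Mbp."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return (1.0 / rate) / (morgans_per_bp * 1e6)


def emission_probs(
    genotype: int, freq_a1: float, epsilon: float
) -> tuple[float, float]:
    """Emission probability of one genotype under HBD and non-HBD states."""
    if genotype == MISSING or np.isnan(freq_a1):
        return 1.0, 1.0
    f = float(freq_a1)
    hw = (f * f, 2 * f * (1 - f), (1 - f) * (1 - f))[genotype]
    copy = (f, 0.0, 1 - f)[genotype]
    return (1 - epsilon) * copy + epsilon * hw, hw


def _emission_matrix(
    genotypes: np.ndarray, freqs: np.ndarray, epsilon: float, n_classes: int
) -> np.ndarray:
    """(n_markers, n_classes) emissions; HBD classes share one column value."""
    g = np.asarray(genotypes)
    f = np.asarray(freqs, dtype=float)
    hw_all = np.stack([f * f, 2 * f * (1 - f), (1 - f) ** 2], axis=1)
    copy_all = np.stack([f, np.zeros_like(f), 1 - f], axis=1)
    uninformative = (g == MISSING) | np.isnan(f)
    g_safe = np.where(uninformative, 0, g)
    hw = hw_all[np.arange(len(g)), g_safe]
    copy = copy_all[np.arange(len(g)), g_safe]
    hbd = (1 - epsilon) * copy + epsilon * hw
    out = np.empty((len(g), n_classes))
    out[:, :-1] = hbd[:, None]
    out[:, -1] = hw
    out[uninformative] = 1.0
    return out


def transition_matrix(d_morgans: float, params: HBDParameters) -> np.ndarray:
    """Inter-marker transition matrix at genetic distance ``d`` Morgans.

    Entry (c, c') = exp(-R_c d) [c = c'] + (1 - exp(-R_c d)) mixing[c']:
    either the current segment continues, or it ends (sooner for
    higher-rate classes) and a new segment class is drawn from the mixing.
    """
    if d_morgans < 0:
        raise ValueError("distance must be non-negative")
    rates = params.all_rates
    mixing = params.mixing_or_uniform
    stay = np.exp(-rates * d_morgans)
    return np.diag(stay) + (1 - stay)[:, None] * mixing[None, :]


def _chain_layout(chromosomes: np.ndarray, positions_morgan: np.ndarray):
    """Per-marker stay probabilities scaffold: chromosome starts and
    inter-marker distances (0 at chromosome starts)."""
    chrom = np.asarray(chromosomes)
    pos = np.asarray(positions_morgan, dtype=float)
    t = len(chrom)
    is_start = np.ones(t, dtype=bool)
    is_start[1:] = chrom[1:] != chrom[:-1]
    d = np.zeros(t)
    d[1:] = np.where(is_start[1:], 0.0, pos[1:] - pos[:-1])
    if np.any(d < 0):
        raise ValueError("markers must be position-sorted within chromosomes")
    return is_start, d


class NonFiniteLikelihoodError(FloatingPointError):
    def __init__(self, marker_index: int):
        super().__init__(
            f"non-finite likelihood at marker index {marker_index}: every class "
            "has zero emission (frequencies inconsistent with the genotypes?)"
        )
        self.marker_index = marker_index


def _forward_backward_batch(
    emis: np.ndarray,  # (B, T, K)
    stay: np.ndarray,  # (T, K); stay[t] applies between markers t-1 and t
    is_start: np.ndarray,  # (T,)
    mixing: np.ndarray,  # (B, K)
):
    """Scaled forward-backward for a batch of individuals sharing one map.

    Returns (gamma, loglik, alpha_hat, beta_scaled, c) where gamma are
    posteriors, c the per-step scaling factors, and beta_scaled satisfies
    gamma = alpha_hat * beta_scaled.
    """
    b, t, k = emis.shape
    alpha = np.empty((b, t, k))
    c = np.empty((b, t))
    for step in range(t):
        if is_start[step]:
            pred = mixing
        else:
            prev = alpha[:, step - 1]
            s = stay[step]
            change = (prev * (1 - s)).sum(axis=1, keepdims=True)
            pred = prev * s + mixing * change
        a = pred * emis[:, step]
        c_step = a.sum(axis=1)
        if not np.all(np.isfinite(c_step)) or np.any(c_step <= 0):
            raise NonFiniteLikelihoodError(step)
        alpha[:, step] = a / c_step[:, None]
        c[:, step] = c_step

    beta = np.empty((b, t, k))
    beta[:, t - 1] = 1.0
    for step in range(t - 2, -1, -1):
        if is_start[step + 1]:
            beta[:, step] = 1.0
            continue
        tmp = emis[:, step + 1] * beta[:, step + 1]
        s = stay[step + 1]
        pooled = (mixing * tmp).sum(axis=1, keepdims=True)
        beta[:, step] = (tmp * s + (1 - s) * pooled) / c[:, step + 1][:, None]

    gamma = alpha * beta
    loglik = np.log(c).sum(axis=1)
    return gamma, loglik, alpha, beta, c


def _expected_segment_counts(emis, stay, is_start, mixing, alpha, beta, c):
    """E-step: expected number of segments entering each class, counting the
    initial segment of every chromosome plus every inter-marker change."""
    b, t, k = emis.shape
    counts = np.zeros((b, k))
    gamma = alpha * beta
    for step in range(t):
        if is_start[step]:
            counts += gamma[:, step]
            continue
        s = stay[step]
        change_mass = (alpha[:, step - 1] * (1 - s)).sum(axis=1, keepdims=True)
        tmp = emis[:, step] * beta[:, step]
        counts += change_mass * mixing * tmp / c[:, step][:, None]
    return counts


def _em_step(emis, stay, is_start, mixing):
    """One EM iteration: forward pass, then a fused backward pass that
    accumulates the expected segment-entry counts on the fly.

    Returns (loglik, updated mixing).
    """
    b, t, k = emis.shape
    alpha = np.empty((b, t, k))
    c = np.empty((b, t))
    for step in range(t):
        if is_start[step]:
            pred = mixing
        else:
            prev = alpha[:, step - 1]
            s = stay[step]
            change = (prev * (1 - s)).sum(axis=1, keepdims=True)
            pred = prev * s + mixing * change
        a = pred * emis[:, step]
        c_step = a.sum(axis=1)
        if not np.all(np.isfinite(c_step)) or np.any(c_step <= 0):
            raise NonFiniteLikelihoodError(step)
        alpha[:, step] = a / c_step[:, None]
        c[:, step] = c_step

    counts = np.zeros((b, k))
    beta = np.ones((b, k))
    for step in range(t - 1, -1, -1):
        if is_start[step]:
            counts += alpha[:, step] * beta
            if step > 0:
                beta = np.ones((b, k))
            continue
        # contribution of the change event between step-1 and step
        s = stay[step]
        tmp = emis[:, step] * beta
        change_mass = (alpha[:, step - 1] * (1 - s)).sum(axis=1, keepdims=True)
        counts += change_mass * mixing * tmp / c[:, step][:, None]
        pooled = (mixing * tmp).sum(axis=1, keepdims=True)
        beta = (tmp * s + (1 - s) * pooled) / c[:, step][:, None]

    loglik = np.log(c).sum(axis=1)
    return loglik, counts / counts.sum(axis=1, keepdims=True)


def _batch_em(emis, stay, is_start, mixing0, tol, max_iter):
    mixing = np.broadcast_to(mixing0, (emis.shape[0], emis.shape[2])).copy()
    history = []
    prev_ll = None
    for _ in range(max_iter):
        ll, new_mixing = _em_step(emis, stay, is_start, mixing)
        history.append(ll)
        if prev_ll is not None and np.all(np.abs(ll - prev_ll) < tol):
            break
        prev_ll = ll
        mixing = new_mixing
    gamma, ll, *_ = _forward_backward_batch(emis, stay, is_start, mixing)
    history.append(ll)
    return mixing, gamma, ll, np.vstack(history)


def forward_backward(
    genotypes: np.ndarray,
    chromosomes: np.ndarray,
    positions_morgan: np.ndarray,
    freqs: np.ndarray,
    params: HBDParameters,
) -> HBDPosterior:
    """Posterior class probabilities for one individual's genotype vector."""
    k = params.n_classes
    emis = _emission_matrix(genotypes, freqs, params.epsilon, k)[None]
    is_start, d = _chain_layout(chromosomes, positions_morgan)
    stay = np.exp(-params.all_rates[None, :] * d[:, None])
    mixing = params.mixing_or_uniform[None]
    gamma, ll, *_ = _forward_backward_batch(emis, stay, is_start, mixing)
    return HBDPosterior(
        probs=gamma[0], log_likelihood=float(ll[0]), rates=params.all_rates
    )


def em_fit(
    genotypes: np.ndarray,
    chromosomes: np.ndarray,
    positions_morgan: np.ndarray,
    freqs: np.ndarray,
    params: HBDParameters,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[HBDParameters, HBDPosterior]:
    """Estimate the mixing coefficients of one individual by EM.

    Rates are never updated; initialization is uniform over classes unless
    ``params.mixing`` is set, and the fit is deterministic.
    """
    k = params.n_classes
    emis = _emission_matrix(genotypes, freqs, params.epsilon, k)[None]
    is_start, d = _chain_layout(chromosomes, positions_morgan)
    stay = np.exp(-params.all_rates[None, :] * d[:, None])
    mixing, gamma, ll, history = _batch_em(
        emis, stay, is_start, params.mixing_or_uniform, tol, max_iter
    )
    fitted = replace(params, mixing=mixing[0])
    posterior = HBDPosterior(
        probs=gamma[0], log_likelihood=float(ll[0]), rates=params.all_rates
    )
    return fitted, posterior


def f_g(posterior: HBDPosterior) -> float:
    """Genome-wide inbreeding: mean total HBD posterior over markers."""
    return float(posterior.hbd_mass.mean())


def f_g_t(posterior: HBDPosterior, threshold_rate: float) -> float:
    """Inbreeding relative to a base population ~T/2 generations ago: mean
    posterior mass of HBD classes with rate <= T."""
    if threshold_rate <= 0:
        raise ValueError("threshold must be positive")
    hbd_rates = posterior.rates[:-1]
    keep = hbd_rates <= threshold_rate
    return float(posterior.probs[:, :-1][:, keep].sum(axis=1).mean())


def partition_genome(posteriors: Sequence[HBDPosterior]) -> pd.DataFrame:
    """Per-individual genome proportions of every class (non-HBD last);
    the row sum over HBD classes equals each individual's F_G."""
    rates = posteriors[0].rates
    cols = [f"R={r:g}" for r in rates[:-1]] + ["non-HBD"]
    return pd.DataFrame([p.class_means for p in posteriors], columns=cols)


# ---------------------------------------------------------------------------
# Model / Results interface


class HBDMixtureModel:
    """MixKR HBD mixture model for every individual of a dataset.

    Parameters
    ----------
    dataset
        Genotypes with map and breed labels.
    rates
        HBD class rates, non-decreasing (default 2, 4, ..., 64).
    non_hbd_rate
        Fixed rate of the non-HBD class (default 64, the most ancient
        class; it is never estimated).
    epsilon
        Genotyping-error probability of the emission model.
    allele_freqs
        Optional explicit per-marker allele-1 frequencies.  By default
        frequencies are estimated within each breed from the sample itself.
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        rates: Sequence[float] = DEFAULT_HBD_RATES,
        non_hbd_rate: float = DEFAULT_NON_HBD_RATE,
        epsilon: float = 0.001,
        allele_freqs: np.ndarray | None = None,
    ):
        self.dataset = dataset
        self.params = HBDParameters(
            rates=tuple(float(r) for r in rates),
            non_hbd_rate=float(non_hbd_rate),
            epsilon=float(epsilon),
            morgans_per_bp=dataset.map.morgans_per_bp,
        )
        self.allele_freqs = allele_freqs

    def fit(self, tol: float = 1e-6, max_iter: int = 1000) -> "HBDMixtureResults":
        ds = self.dataset
        params = self.params
        k = params.n_classes
        is_start, d = _chain_layout(ds.map.chromosome, ds.map.genetic_pos_morgan)
        stay = np.exp(-params.all_rates[None, :] * d[:, None])

        mixing_all = np.empty((ds.n_individuals, k))
        gamma_all = np.empty((ds.n_individuals, ds.n_markers, k))
        ll_all = np.empty(ds.n_individuals)
        histories: dict[int, np.ndarray] = {}

        for breed in ds.breed_names:
            idx = ds.individuals_of(breed)
            if self.allele_freqs is not None:
                freqs = self.allele_freqs
            else:
                freqs, _ = allele_frequencies(ds, breed)
            emis = np.stack(
                [
                    _emission_matrix(ds.genotypes[i], freqs, params.epsilon, k)
                    for i in idx
                ]
            )
            mixing, gamma, ll, history = _batch_em(
                emis, stay, is_start, params.mixing_or_uniform, tol, max_iter
            )
            mixing_all[idx] = mixing
            gamma_all[idx] = gamma
            ll_all[idx] = ll
            for col, i in enumerate(idx):
                histories[int(i)] = history[:, col]

        posteriors = [
            HBDPosterior(
                probs=gamma_all[i], log_likelihood=float(ll_all[i]),
                rates=params.all_rates,
            )
            for i in range(ds.n_individuals)
        ]
        return HBDMixtureResults(
            model=self,
            mixing=mixing_all,
            posteriors=posteriors,
            log_likelihood=ll_all,
            loglik_history={i: histories[i] for i in histories},
        )


class HBDMixtureResults:
    """Per-individual MixKR estimates: mixing coefficients, HBD posteriors,
    genome-wide inbreeding and the genome partition over classes."""

    def __init__(self, model, mixing, posteriors, log_likelihood, loglik_history):
        self.model = model
        self.mixing = mixing
        self.posteriors = posteriors
        self.log_likelihood = log_likelihood
        self.loglik_history = loglik_history

    @property
    def rates(self) -> np.ndarray:
        return self.model.params.all_rates

    @property
    def f_g(self) -> np.ndarray:
        """Genome-wide inbreeding coefficient per individual."""
        return np.array([f_g(p) for p in self.posteriors])

    def f_g_t(self, threshold_rate: float) -> np.ndarray:
        """Per-individual inbreeding restricted to classes with R <= T."""
        return np.array([f_g_t(p, threshold_rate) for p in self.posteriors])

    def genome_partition(self) -> pd.DataFrame:
        out = partition_genome(self.posteriors)
        out.insert(0, "breed", self.model.dataset.breeds)
        out.index = self.model.dataset.ids
        return out

    def summary(self, thresholds: Sequence[float] = (4.0, 16.0, 64.0)) -> pd.DataFrame:
        """Breed-level summary: mean F_G, mean F_G-T at the requested rate
        thresholds and the mean non-HBD genome proportion."""
        ds = self.model.dataset
        frame = pd.DataFrame(
            {
                "breed": ds.breeds,
                "F_G": self.f_g,
                "non_HBD": [p.class_means[-1] for p in self.posteriors],
            },
            index=ds.ids,
        )
        for t in thresholds:
            frame[f"F_G-T(T={t:g})"] = self.f_g_t(t)
        return frame.groupby("breed").mean()

    def to_frame(self) -> pd.DataFrame:
        """Per-individual table of mixing estimates, F_G and log-likelihood."""
        ds = self.model.dataset
        cols = [f"mix_R={r:g}" for r in self.rates[:-1]] + ["mix_non_HBD"]
        frame = pd.DataFrame(self.mixing, index=ds.ids, columns=cols)
        frame.insert(0, "breed", ds.breeds)
        frame["F_G"] = self.f_g
        frame["log_likelihood"] = self.log_likelihood
        return frame
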