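"""Iterative Cas9 selection dynamics over clone classes.

One induction round kills every cell whose plasmid is cleaved.  A clone
survives if it carries an Acr (protection probability ``acr_protection``), if
its host has lost Cas9 function (probability ``lof_survival``, the empirical
escape rate of ~1e-4..1e-5 per transformant), or if every intact wild-type
target site escapes cleavage (per-site probability ``site_escape_prob``).
Sites that are already point-mutant or recombined away contribute no risk.

Two propagators share the same summaries: a deterministic closed form on
expected frequencies, and a binomial Monte-Carlo twin for finite populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_library import CloneGenotype, LibraryModel


class LibraryExtinctError(RuntimeError):
    """Raised when no clone class survives an induction round."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"library extinct at iteration {iteration}")


@dataclass(frozen=True)
class SelectionParams:
    """Per-round survival probabilities and the iteration schedule."""

    lof_survival: float = 1e-4        # lambda: Cas9 loss-of-function escape
    site_escape_prob: float = 0.0     # mu: per-site target escape per round
    acr_protection: float = 1.0
    n_iterations: int = 2
    n_target_sites: int = 2

    def __post_init__(self) -> None:
        for name in ("lof_survival", "site_escape_prob", "acr_protection"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def survival_probability(genotype: CloneGenotype,
                         params: SelectionParams) -> float:
    """Probability that one clone's plasmid survives one induction round.

    Acr carriage dominates; Cas9 loss of function protects unconditionally;
    otherwise the host escapes with probability lambda or every intact
    wild-type site independently escapes with probability mu.
    """
    if genotype.has_acr:
        return params.acr_protection
    if genotype.cas9_lof:
        return 1.0
    return _class_survival(genotype.n_intact_wild_type_sites, params)


def _class_survival(n_wild_type_sites: int, params: SelectionParams) -> float:
    lam, mu = params.lof_survival, params.site_escape_prob
    return lam + (1.0 - lam) * mu ** n_wild_type_sites


@dataclass
class SelectionOutcome:
    """Per-iteration class frequencies and survival summaries.

    ``frequencies[t]`` is the class-frequency vector after t iterations
    (``frequencies[0]`` is the input library).  ``kanr_proportion[t]`` is the
    fraction of cells retaining the plasmid through round t+1 (sum of
    f_j * s_j), ``fold_reduction[t]`` its reciprocal, and
    ``enrichment_factor[t][j]`` = f_j(t+1) / f_j(t).
    """

    class_labels: list[str]
    survival: np.ndarray
    frequencies: list[np.ndarray] = field(default_factory=list)
    kanr_proportion: list[float] = field(default_factory=list)
    fold_reduction: list[float] = field(default_factory=list)
    enrichment_factor: list[np.ndarray] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.kanr_proportion)

    def final_frequency(self, label: str) -> float:
        return float(self.frequencies[-1][self.class_labels.index(label)])

    def cumulative_enrichment(self, label: str) -> float:
        j = self.class_labels.index(label)
        f0, ft = self.frequencies[0][j], self.frequencies[-1][j]
        return float(ft / f0) if f0 > 0 else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, f in enumerate(self.frequencies):
            for j, lab in enumerate(self.class_labels):
                rows.append({"iteration": t, "class": lab,
                             "frequency": float(f[j])})
        return pd.DataFrame(rows)


def _classes_from_model(model: LibraryModel,
                        params: SelectionParams) -> tuple[list[str], np.ndarray, np.ndarray]:
    df = model.survival_classes()
    labels, freqs, surv = [], [], []
    for _, row in df.iterrows():
        if row["has_acr"]:
            s = params.acr_protection
            lab = "acr"
        elif row["cas9_lof"]:
            s = 1.0
            lab = f"lof_wt{int(row['n_wild_type_sites'])}"
        else:
            s = _class_survival(int(row["n_wild_type_sites"]), params)
            lab = f"wt{int(row['n_wild_type_sites'])}"
        labels.append(lab)
        freqs.append(float(row["frequency"]))
        surv.append(s)
    return labels, np.asarray(freqs), np.asarray(surv)


def _as_classes(model, params):
    """Accept a LibraryModel or explicit (labels, frequencies, survivals)."""
    if isinstance(model, LibraryModel):
        return _classes_from_model(model, params)
    labels, freqs, surv = model
    freqs = np.asarray(freqs, dtype=float)
    surv = np.asarray(surv, dtype=float)
    if not np.isclose(freqs.sum(), 1.0, atol=1e-9):
        raise ValueError("class frequencies must sum to 1")
    return list(labels), freqs, surv


def propagate_expected(model, params: SelectionParams) -> SelectionOutcome:
    """Deterministic expected-frequency propagation.

    Per iteration f_j' = f_j s_j / sum_k f_k s_k; the normalizer is the
    Kan^R proportion of that round.
    """
    labels, f, s = _as_classes(model, params)
    out = SelectionOutcome(class_labels=labels, survival=s, frequencies=[f])
    for t in range(params.n_iterations):
        z = float(np.dot(f, s))
        if z <= 0.0:
            raise LibraryExtinctError(t)
        f_next = f * s / z
        out.kanr_proportion.append(z)
        out.fold_reduction.append(1.0 / z)
        with np.errstate(divide="ignore", invalid="ignore"):
            out.enrichment_factor.append(np.where(f > 0, f_next / f, np.nan))
        out.frequencies.append(f_next)
        f = f_next
    return out


def _initial_counts(freqs: np.ndarray, n_cells: int) -> np.ndarray:
    """Largest-remainder rounding of expected counts to integers summing to n."""
    raw = freqs * n_cells
    counts = np.floor(raw).astype(np.int64)
    short = n_cells - int(counts.sum())
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def propagate_monte_carlo(model, params: SelectionParams, n_cells: int,
                          seed: int = 0) -> SelectionOutcome:
    """Stochastic twin of :func:`propagate_expected`.

    Each round draws surviving cell counts binomially per class and
    renormalizes; between rounds the population regrows deterministically to
    ``n_cells`` (largest-remainder scaling of the surviving frequencies), so
    selection is the only source of noise and the no-selection limit leaves
    frequencies exactly unchanged.  The initial counts are the
    largest-remainder rounding of the expected class counts, so a one-in-N
    clone at n_cells = N is present in every replicate.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    labels, f, s = _as_classes(model, params)
    rng = np.random.default_rng(seed)
    counts = _initial_counts(f, n_cells)
    f = counts / counts.sum()
    out = SelectionOutcome(class_labels=labels, survival=s, frequencies=[f])
    for t in range(params.n_iterations):
        survivors = rng.binomial(counts, s)
        total = int(survivors.sum())
        if total == 0:
            raise LibraryExtinctError(t)
        z = total / counts.sum()
        f_next = survivors / total
        out.kanr_proportion.append(float(z))
        out.fold_reduction.append(1.0 / z)
        with np.errstate(divide="ignore", invalid="ignore"):
            out.enrichment_factor.append(np.where(f > 0, f_next / f, np.nan))
        out.frequencies.append(f_next)
        f = f_next
        if t + 1 < params.n_iterations:
            counts = _initial_counts(f_next, n_cells)
        else:
            counts = survivors
    return out


NO_DETECTABLE_SIZE = None


def minimum_detectable_frequency(params: SelectionParams,
                                 majority_threshold: float = 0.5,
                                 max_exponent: int = 12):
    """Largest power-of-ten library size from which a single Acr clone ends in
    the majority after the configured number of selection iterations.

    Scans N = 10^1 .. 10^max_exponent, placing one Acr clone at frequency 1/N
    against a wild-type background, and returns the largest N whose final Acr
    frequency exceeds ``majority_threshold`` (``None`` if no N qualifies).

    The propagation uses the rare-clone limit (background depletion by the
    Acr clone itself neglected): f' = f s_acr / (f s_acr + s_bg).  At the
    sizes this bound cares about (f of order the per-round escape rate raised
    to the iteration count) the exact renormalized update differs only by
    O(f) terms, and the limit keeps the bound from flipping on those terms
    exactly at the majority boundary.
    """
    if not (0.0 < majority_threshold < 1.0):
        raise ValueError("majority_threshold must lie in (0, 1)")
    s_acr = params.acr_protection
    s_bg = _class_survival(params.n_target_sites, params)
    best = NO_DETECTABLE_SIZE
    for e in range(1, max_exponent + 1):
        f = 1.0 / 10 ** e
        for _ in range(params.n_iterations):
            z = f * s_acr + s_bg
            if z <= 0.0:
                f = 0.0
                break
            f = f * s_acr / z
        if f > majority_threshold:
            best = 10 ** e
    return best
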