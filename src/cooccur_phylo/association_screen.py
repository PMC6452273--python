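"""Phylogeny-naive association screening of binary trait pairs.

For every (system, cas) trait pair surviving a frequency filter this stage
builds the 2x2 contingency table of joint presence/absence, computes the
phi association coefficient, compares |phi| against frequency-matched
control genes (the delta-phi analysis, aggregated in a one-sided t-test),
and tests each pair's independence with a Fisher exact test under a
Bonferroni correction over all tested pairs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from cooccur_phylo.trait_io import TraitMatrix

logger = logging.getLogger(__name__)


class UndefinedPhiError(ValueError):
    """Phi is undefined because a margin of the contingency table is zero."""


@dataclass(frozen=True)
class ContingencyTable:
    """Joint presence/absence counts for a trait pair (X, Y).

    a = both present, b = X only, c = Y only, d = both absent.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name, v in zip("abcd", (self.a, self.b, self.c, self.d)):
            if v < 0 or v != int(v):
                raise ValueError(f"count {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        """(a+b, c+d, a+c, b+d): X present, X absent, Y present, Y absent."""
        return (
            self.a + self.b,
            self.c + self.d,
            self.a + self.c,
            self.b + self.d,
        )

    def swapped(self) -> "ContingencyTable":
        """The table for the pair (Y, X)."""
        return ContingencyTable(self.a, self.c, self.b, self.d)


@dataclass
class ScreenRecord:
    """Per-pair result of the phylogeny-naive screen."""

    system_id: str
    cas_id: str
    table: ContingencyTable
    phi: float = float("nan")  # NaN when undefined (zero margin)
    control_phis: list = field(default_factory=list)  # |phi| of matched controls
    delta_phi: float = float("nan")
    fisher_p: float = float("nan")
    m_tests: int = 0
    bonferroni_significant: bool = False

    @property
    def testable(self) -> bool:
        return not math.isnan(self.phi)

    @property
    def sign(self) -> int:
        """Screen-stage signed call: sign(phi) if Bonferroni-significant."""
        if not self.bonferroni_significant or not self.testable or self.phi == 0:
            return 0
        return 1 if self.phi > 0 else -1


@dataclass(frozen=True)
class DeltaPhiResult:
    """One-sided t-test of H1: mean delta-phi > 0."""

    mean: float
    t: float
    p: float
    n: int


def frequency_filter(
    m: TraitMatrix, lo: float = 0.01, hi: float = 0.99
) -> list[str]:
    """Trait ids whose presence frequency f satisfies lo < f < hi (strict)."""
    if lo >= hi:
        raise ValueError(f"lo must be < hi, got lo={lo}, hi={hi}")
    freqs = m.frequencies()
    kept = []
    for trait, f in freqs.items():
        if lo < f < hi:
            kept.append(trait)
        else:
            logger.info("frequency filter excluded %s (f=%.4f)", trait, f)
    return kept


def contingency(m: TraitMatrix, x: str, y: str) -> ContingencyTable:
    """2x2 contingency table of joint presence/absence for traits x and y."""
    for trait in (x, y):
        if trait not in m.values.columns:
            raise KeyError(f"unknown trait id {trait!r}")
    vx = m.values[x].to_numpy()
    vy = m.values[y].to_numpy()
    a = int(np.sum((vx == 1) & (vy == 1)))
    b = int(np.sum((vx == 1) & (vy == 0)))
    c = int(np.sum((vx == 0) & (vy == 1)))
    d = int(np.sum((vx == 0) & (vy == 0)))
    return ContingencyTable(a, b, c, d)


def phi(t: ContingencyTable) -> float:
    """Phi coefficient (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)).

    Equals the Pearson correlation of the two binary indicator vectors.
    Raises :class:`UndefinedPhiError` when any margin is zero (the pair is
    untestable, not zero-associated).
    """
    margins = t.margins()
    if any(mg == 0 for mg in margins):
        raise UndefinedPhiError(
            f"phi undefined: zero margin in table ({t.a},{t.b},{t.c},{t.d})"
        )
    num = t.a * t.d - t.b * t.c
    denom = math.sqrt(math.prod(margins))
    return num / denom


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for a contingency table.

    Uses the minimum-likelihood convention (sum of hypergeometric
    probabilities of all same-margin tables no more probable than the
    observed one), as implemented by :func:`scipy.stats.fisher_exact`.
    """
    if t.n < 1:
        raise ValueError("empty contingency table")
    _, p = scipy.stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return float(min(p, 1.0))


def match_controls(
    target: str,
    pool,
    m: TraitMatrix,
    k: int = 10,
    margin: float = 0.01,
    seed: int = 0,
) -> list[str]:
    """Sample ``k`` control traits frequency-matched to ``target``.

    Controls are drawn without replacement, uniformly among pool members
    whose presence frequency lies within ``margin`` (absolute) of the
    target's.  If fewer than ``k`` qualify the margin is widened in +0.01
    steps (each widening logged) up to 0.5.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("control pool is empty")
    if k > len(pool):
        raise ValueError(
            f"requested k={k} controls but pool has only {len(pool)}"
        )
    f_target = m.frequency(target)
    pool_freqs = np.array([m.frequency(c) for c in pool])
    current = margin
    while True:
        eligible = [
            c for c, f in zip(pool, pool_freqs) if abs(f - f_target) <= current
        ]
        if len(eligible) >= k:
            break
        if current >= 0.5:
            raise ValueError(
                f"only {len(eligible)} controls within margin 0.5 of "
                f"{target!r} (f={f_target:.4f}); need {k}"
            )
        current = min(current + 0.01, 0.5)
        logger.info(
            "match_controls: widened margin to %.2f for %s", current, target
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[i] for i in sorted(chosen)]


def delta_phi_test(deltas) -> DeltaPhiResult:
    """One-sample, one-sided t-test of H1: mean(delta-phi) > 0.

    Degenerate zero-variance input returns p = 0 if the common value is
    positive, else p = 1 (with a warning).
    """
    deltas = np.asarray(list(deltas), dtype=float)
    if deltas.size < 2:
        raise ValueError(f"need >= 2 delta-phi values, got {deltas.size}")
    mean = float(deltas.mean())
    sd = float(deltas.std(ddof=1))
    if sd == 0.0:
        warnings.warn("zero-variance delta-phi sample; degenerate t-test")
        p = 0.0 if mean > 0 else 1.0
        t = math.inf if mean > 0 else (-math.inf if mean < 0 else 0.0)
        if mean == 0.0:
            p = 1.0
        return DeltaPhiResult(mean, t, p, int(deltas.size))
    t = mean / (sd / math.sqrt(deltas.size))
    p = float(scipy.stats.t.sf(t, df=deltas.size - 1))
    return DeltaPhiResult(mean, float(t), p, int(deltas.size))


def bonferroni(pvals: dict, alpha: float = 0.05) -> dict:
    """Bonferroni significance calls: p <= alpha / m over the m tested pairs."""
    m = len(pvals)
    if m < 1:
        raise ValueError("no p-values supplied")
    threshold = alpha / m
    return {pair: (p <= threshold) for pair, p in pvals.items()}


def _control_seed(seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def screen(
    m: TraitMatrix,
    k_controls: int = 10,
    margin: float = 0.01,
    alpha: float = 0.05,
    seed: int = 0,
    lo: float = 0.01,
    hi: float = 0.99,
) -> tuple[list[ScreenRecord], DeltaPhiResult]:
    """Run the full phylogeny-naive screen over all (system, cas) pairs.

    Traits are frequency-filtered (strict lo < f < hi); each retained system
    trait is matched to ``k_controls`` frequency-matched controls; each
    (system, cas) pair gets a contingency table, phi, delta-phi versus the
    controls, and a Fisher exact p; Bonferroni correction runs over the
    pairs actually tested.  Pairs with a zero margin are reported untestable
    (phi = NaN) and excluded from both the delta-phi aggregate and the
    Fisher/Bonferroni family.
    """
    kept = set(frequency_filter(m, lo, hi))
    systems = [t for t in m.traits_in_group("system") if t in kept]
    cas = [t for t in m.traits_in_group("cas") if t in kept]
    controls = [t for t in m.traits_in_group("control") if t in kept]
    if not systems or not cas:
        raise ValueError(
            f"need >= 1 system and >= 1 cas trait after filtering "
            f"(got {len(systems)} system, {len(cas)} cas)"
        )
    if len(controls) < k_controls:
        raise ValueError(
            f"need >= {k_controls} control traits after filtering, "
            f"got {len(controls)}"
        )

    matched = {
        s: match_controls(s, controls, m, k_controls, margin, _control_seed(seed, i))
        for i, s in enumerate(systems)
    }

    records = []
    for s in systems:
        for ca in cas:
            table = contingency(m, s, ca)
            rec = ScreenRecord(system_id=s, cas_id=ca, table=table)
            try:
                rec.phi = phi(table)
            except UndefinedPhiError:
                rec.phi = float("nan")
                logger.warning("pair (%s, %s) untestable: zero margin", s, ca)
                records.append(rec)
                continue
            ctrl_phis = []
            for ctrl in matched[s]:
                try:
                    ctrl_phis.append(abs(phi(contingency(m, ctrl, ca))))
                except UndefinedPhiError:
                    logger.warning(
                        "control %s untestable against %s; dropped", ctrl, ca
                    )
            rec.control_phis = ctrl_phis
            if ctrl_phis:
                rec.delta_phi = abs(rec.phi) - float(np.mean(ctrl_phis))
            rec.fisher_p = fisher_exact(table)
            records.append(rec)

    tested = [r for r in records if r.testable]
    if tested:
        calls = bonferroni(
            {(r.system_id, r.cas_id): r.fisher_p for r in tested}, alpha
        )
        for r in tested:
            r.m_tests = len(tested)
            r.bonferroni_significant = calls[(r.system_id, r.cas_id)]

    deltas = [r.delta_phi for r in tested if not math.isnan(r.delta_phi)]
    if len(deltas) < 2:
        raise ValueError("fewer than 2 testable pairs; delta-phi test undefined")
    dp = delta_phi_test(deltas)
    return records, dp
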