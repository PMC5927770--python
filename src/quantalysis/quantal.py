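"""Quantal content and homeostatic-potentiation (PHP) classification.

Quantal content (QC) — vesicles released per action potential — is measured
as the ratio of a cell's mean evoked amplitude to its mean miniature
amplitude, and equals N * p under the binomial model regardless of quantal
size.  PHP is the retrograde compensation that keeps the evoked response
constant when quantal size drops; a condition expresses PHP when minis are
significantly reduced, the evoked response is statistically unchanged, and
QC is significantly increased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import StatResult, two_group_test


@dataclass
class QuantalSummary:
    """Per-cell summary: mini mean, evoked mean, and their ratio (QC)."""

    cell_id: str
    muscle: str
    genotype: str
    mepsp_mean: float
    epsp_mean: float
    n_minis: int
    n_evoked: int
    mode: str = "current_clamp"
    rin: float | None = None      # MOhm, pass-through quality metric
    vrest: float | None = None    # mV

    def __post_init__(self):
        if self.n_minis < 1 or self.n_evoked < 1:
            raise ValueError("means must come from at least one event")
        if self.mepsp_mean <= 0:
            raise ValueError("mepsp_mean must be positive")

    @property
    def quantal_content(self) -> float:
        return self.epsp_mean / self.mepsp_mean


@dataclass
class PHPReport:
    """Outcome of the three-part PHP test for one (genotype, muscle)."""

    genotype: str
    muscle: str
    baseline_genotype: str
    normalized_mepsp_pct: float
    normalized_qc_pct: float
    epsp_maintained: bool
    php_expressed: bool
    tests: dict = field(default_factory=dict)  # label -> StatResult


def quantal_content(epsp_mean: float, mepsp_mean: float,
                    mode=None, mini_mode=None) -> float:
    """Evoked mean divided by miniature mean (same units, same mode)."""
    if mode is not None and mini_mode is not None and mode != mini_mode:
        raise ValueError("evoked and mini recordings are from different "
                         f"modes: {mode!r} vs {mini_mode!r}")
    if mepsp_mean <= 0:
        raise ValueError("mepsp_mean must be positive")
    return epsp_mean / mepsp_mean


def normalize_to_baseline(values, baseline_values):
    """Percent of baseline, 100 * mean(values) / mean(baseline).

    Returns ``(percent, sem_percent)`` with the SEM propagated through the
    ratio of means by the first-order delta method:
    Var(x̄/ȳ) ≈ (x̄/ȳ)² (SE_x²/x̄² + SE_y²/ȳ²) for independent groups.
    """
    values = np.asarray(values, dtype=float)
    baseline = np.asarray(baseline_values, dtype=float)
    if values.size == 0 or baseline.size == 0:
        raise ValueError("empty inputs")
    mb = baseline.mean()
    if mb <= 0:
        raise ValueError("baseline mean must be positive")
    mv = values.mean()
    ratio = mv / mb
    se_v = values.std(ddof=1) / np.sqrt(values.size) if values.size > 1 else 0.0
    se_b = (baseline.std(ddof=1) / np.sqrt(baseline.size)
            if baseline.size > 1 else 0.0)
    rel = (se_v / mv) ** 2 if mv != 0 else 0.0
    rel += (se_b / mb) ** 2
    return 100.0 * ratio, 100.0 * abs(ratio) * np.sqrt(rel)


def php_assessment(test_cells, control_cells, alpha: float = 0.05,
                   equal_var: bool = True) -> PHPReport:
    """Classify PHP expression for a test condition against its control.

    The flag is a conjunction of three Student t comparisons at ``alpha``:
    mini amplitude significantly *reduced*, evoked amplitude *not*
    significantly different, and quantal content significantly *increased*.
    """
    test_cells = list(test_cells)
    control_cells = list(control_cells)
    if not test_cells or not control_cells:
        raise ValueError("both groups must be non-empty")
    if len(test_cells) < 2 or len(control_cells) < 2:
        raise ValueError("need n >= 2 per group for a variance estimate")
    muscles = {c.muscle for c in test_cells} | {c.muscle for c in control_cells}
    if len(muscles) != 1:
        raise ValueError(f"mixed muscles in comparison: {muscles}")
    modes = {c.mode for c in test_cells} | {c.mode for c in control_cells}
    if len(modes) != 1:
        raise ValueError(f"mixed recording modes in comparison: {modes}")

    def col(cells, attr):
        return np.array([getattr(c, attr) for c in cells])

    t_mini = two_group_test(col(test_cells, "mepsp_mean"),
                            col(control_cells, "mepsp_mean"),
                            label="mepsp", equal_var=equal_var)
    t_epsp = two_group_test(col(test_cells, "epsp_mean"),
                            col(control_cells, "epsp_mean"),
                            label="epsp", equal_var=equal_var)
    t_qc = two_group_test(col(test_cells, "quantal_content"),
                          col(control_cells, "quantal_content"),
                          label="quantal_content", equal_var=equal_var)

    mini_reduced = t_mini.p_value < alpha and t_mini.group_means[0] < t_mini.group_means[1]
    epsp_maintained = not (t_epsp.p_value < alpha)
    qc_increased = t_qc.p_value < alpha and t_qc.group_means[0] > t_qc.group_means[1]

    norm_mepsp, _ = normalize_to_baseline(col(test_cells, "mepsp_mean"),
                                          col(control_cells, "mepsp_mean"))
    norm_qc, _ = normalize_to_baseline(col(test_cells, "quantal_content"),
                                       col(control_cells, "quantal_content"))

    return PHPReport(
        genotype=test_cells[0].genotype,
        muscle=test_cells[0].muscle,
        baseline_genotype=control_cells[0].genotype,
        normalized_mepsp_pct=norm_mepsp,
        normalized_qc_pct=norm_qc,
        epsp_maintained=epsp_maintained,
        php_expressed=bool(mini_reduced and epsp_maintained and qc_increased),
        tests={t.label: t for t in (t_mini, t_epsp, t_qc)},
    )
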