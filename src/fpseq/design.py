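"""Experiment designs for two-foreperiod variable-foreperiod tasks.

A design fixes the foreperiod pair, the per-block mix of short / long /
catch trials, the number of test blocks, the catch-trial blank duration and
the inter-trial-interval range.  The built-in presets are the four published
configurations: three non-aging mixes (16 short / 8 long / 8 catch per
32-trial block) and one uniform mix (12 / 12, no catch).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ExperimentDesign:
    """Structure of one two-foreperiod experiment.

    All durations are in milliseconds.  ``practice_mix`` gives the
    (short, long, catch) trial counts of the single practice block that is
    generated when ``practice_included`` is set; practice trials are flagged
    with block index -1 so preprocessing can drop them.
    """

    fp_short: int
    fp_long: int
    n_short_per_block: int
    n_long_per_block: int
    n_catch_per_block: int
    n_test_blocks: int
    catch_blank: int = 0
    iti_min: int = 500
    iti_max: int = 1500
    practice_included: bool = False
    practice_mix: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if not self.fp_short < self.fp_long:
            raise ValueError(
                f"fp_short ({self.fp_short}) must be < fp_long ({self.fp_long})"
            )
        for name in ("n_short_per_block", "n_long_per_block", "n_catch_per_block",
                     "n_test_blocks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_short_per_block + self.n_long_per_block < 1:
            raise ValueError("a block needs at least one regular trial")
        if self.iti_min > self.iti_max:
            raise ValueError("iti_min must be <= iti_max")

    @property
    def n_trials_per_block(self) -> int:
        return self.n_short_per_block + self.n_long_per_block + self.n_catch_per_block

    @property
    def n_regular_per_block(self) -> int:
        return self.n_short_per_block + self.n_long_per_block


# Published presets.  Catch blanks are one second longer than the long
# foreperiod; exp4 draws foreperiods uniformly and has no catch trials.
_PRESETS: dict[str, ExperimentDesign] = {
    "exp1": ExperimentDesign(400, 1400, 16, 8, 8, 15, catch_blank=2400,
                             practice_included=True, practice_mix=(8, 4, 4)),
    "exp2": ExperimentDesign(50, 200, 16, 8, 8, 15, catch_blank=1200,
                             practice_included=True, practice_mix=(8, 4, 4)),
    "exp3": ExperimentDesign(50, 400, 16, 8, 8, 17, catch_blank=1400,
                             practice_included=True, practice_mix=(8, 4, 4)),
    "exp4": ExperimentDesign(400, 1400, 12, 12, 0, 15,
                             practice_included=True, practice_mix=(6, 6, 0)),
}


def design_preset(experiment_id: str) -> ExperimentDesign:
    """Return one of the four published experiment designs.

    Parameters
    ----------
    experiment_id
        One of ``"exp1"`` (400/1400 ms non-aging), ``"exp2"`` (50/200 ms
        non-aging), ``"exp3"`` (50/400 ms non-aging, 17 blocks) or
        ``"exp4"`` (400/1400 ms uniform, no catch trials).
    """
    try:
        return _PRESETS[experiment_id]
    except KeyError:
        raise ValueError(
            f"unknown experiment preset {experiment_id!r}; "
            f"available presets: {sorted(_PRESETS)}"
        ) from None


def hazard_profile(design: ExperimentDesign) -> tuple[float, ...]:
    """Conditional probability of the imperative stimulus at each critical moment.

    Element k is P(stimulus occurs at critical moment k | it has not occurred
    yet), computed from the per-block trial counts; catch trials contribute
    "no stimulus at any moment".  A non-aging mix yields a constant profile.
    """
    if design.n_regular_per_block < 1:
        raise ValueError("hazard profile undefined: no regular trials in a block")
    n_total = design.n_trials_per_block
    remaining_after_short = n_total - design.n_short_per_block
    p1 = design.n_short_per_block / n_total
    if design.n_long_per_block == 0:
        return (p1,)
    p2 = design.n_long_per_block / remaining_after_short
    return (p1, p2)
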