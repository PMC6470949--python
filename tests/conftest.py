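import numpy as np
import pytest

from swimtraj.loads import SwimmerSeason, TrainingWeek


@pytest.fixture
def rng():
    return np.random.default_rng(20250922)


def random_season(rng, n_weeks: int = 25, swimmer_id: str = "S0") -> SwimmerSeason:
    """A season with positive random volumes in every category."""
    weeks = [
        TrainingWeek(
            week_before_bp=w,
            i1_m=float(rng.uniform(5_000, 25_000)),
            i2_m=float(rng.uniform(5_000, 25_000)),
            i3_m=float(rng.uniform(500, 4_000)),
            i4_m=float(rng.uniform(100, 1_500)),
            i5_m=float(rng.uniform(50, 500)),
            gc_min=float(rng.uniform(30, 150)),
            st_min=float(rng.uniform(10, 90)),
        )
        for w in range(n_weeks, 0, -1)
    ]
    return SwimmerSeason(
        swimmer_id=swimmer_id,
        season_label="t",
        weeks=weeks,
        performance_s=float(rng.uniform(48, 55)),
        m10wp_s=50.0,
    )


@pytest.fixture
def season(rng):
    return random_season(rng)
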