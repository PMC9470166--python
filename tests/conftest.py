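import numpy as np
import pytest

from sipstruct.lickometer import BoutRecord, LickEvent, SessionRecord
from sipstruct.synth import BehaviorParams, CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_session(bouts, animal_id="m01", session_index=1, length_h=2.0,
                 fluid="water", virus="eGFP", pre=46.0, post=45.0, body=25.0):
    return SessionRecord(
        animal_id=animal_id,
        session_index=session_index,
        session_length_h=length_h,
        fluid=fluid,
        virus=virus,
        bottle_weight_pre_g=pre,
        bottle_weight_post_g=post,
        body_weight_g=body,
        bouts=list(bouts),
    )


def simple_bout(start, span=2.0, n_licks=5, lick_duration=0.5):
    return BoutRecord(start=start, end=start + span, n_licks=n_licks,
                      lick_duration=lick_duration)


@pytest.fixture
def tiny_cohort():
    """Nine animals, full six-week schedule, default behavioral parameters."""
    cfg = CohortConfig(
        n_per_class={("water", "ChR2"): 2, ("water", "eGFP"): 3,
                     ("alcohol", "ChR2"): 2, ("alcohol", "eGFP"): 2},
        seed=101,
    )
    return generate_cohort(cfg, BehaviorParams())


def random_events(rng, n, t_max=7200.0, max_len=0.12):
    """Sorted, non-overlapping lick events at random times."""
    onsets = np.sort(rng.uniform(0.0, t_max, n))
    events = []
    prev_off = 0.0
    for o in onsets:
        o = max(o, prev_off + 1e-4)
        ln = rng.uniform(0.02, max_len)
        events.append(LickEvent(o, o + ln))
        prev_off = o + ln
    return events
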