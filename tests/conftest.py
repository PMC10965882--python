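import numpy as np
import pytest

from aerialgaze.events import FixationEvent, SaccadeEvent, Trial
from aerialgaze.synthetic import (
    SynthConfig,
    gen_annotations,
    gen_images,
    gen_scanpaths,
)


def make_fixation(x, y, onset=0.0, dur=200.0, pid="p00", img="img0", first=False):
    return FixationEvent(
        participant_id=pid, image_id=img, onset_ms=onset, offset_ms=onset + dur,
        x_px=x, y_px=y, is_first=first,
    )


def make_saccade(x0, y0, x1, y1, onset=100.0, amp=1.0, pid="p00", img="img0"):
    return SaccadeEvent(
        participant_id=pid, image_id=img, onset_ms=onset,
        start_x_px=x0, start_y_px=y0, end_x_px=x1, end_y_px=y1,
        amplitude_dva=amp,
    )


def make_trial(fixations, saccades=(), pid="p00", img="img0", correct=True,
               trackloss=(), category=None):
    return Trial(
        participant_id=pid, image_id=img, category=category, correct=correct,
        fixations=list(fixations), saccades=list(saccades),
        trackloss_segments=list(trackloss),
    )


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down study: 3 categories x 4 images x 4 observers, 200 px."""
    return SynthConfig(
        n_categories=3,
        images_per_category=4,
        observers=4,
        image_size_px=200,
        seed=42,
    )


@pytest.fixture(scope="session")
def violation_cfg():
    """Small study with every invalid-event type planted at elevated rates."""
    return SynthConfig(
        n_categories=3,
        images_per_category=5,
        observers=6,
        image_size_px=200,
        p_incorrect_trial=0.06,
        p_too_few_fixations_trial=0.04,
        p_trackloss_trial=0.04,
        p_short_fixation=0.05,
        p_out_fixation=0.03,
        p_early_saccade=0.04,
        seed=7,
    )


@pytest.fixture(scope="session")
def synth_study(small_cfg):
    rng = np.random.default_rng(small_cfg.seed)
    images, categories, objects = gen_images(small_cfg, rng)
    annotations = gen_annotations(small_cfg, objects)
    trials, truth = gen_scanpaths(small_cfg, annotations, categories, rng)
    return dict(
        images=images, categories=categories, objects=objects,
        annotations=annotations, trials=trials, truth=truth,
    )


@pytest.fixture(scope="session")
def violation_study(violation_cfg):
    rng = np.random.default_rng(violation_cfg.seed)
    images, categories, objects = gen_images(violation_cfg, rng)
    annotations = gen_annotations(violation_cfg, objects)
    trials, truth = gen_scanpaths(violation_cfg, annotations, categories, rng)
    return dict(
        categories=categories, annotations=annotations, trials=trials, truth=truth,
    )
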