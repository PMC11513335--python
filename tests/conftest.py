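import numpy as np
import pandas as pd
import pytest

from chronomet import (
    ChallengeWindow,
    MetaboliteInfo,
    ProfileDataset,
    StudyDesign,
    TimePoint,
    build_schedule,
)


def make_design(n_tp=6, spacing=30.0, subjects=(1, 2, 3), challenge=True):
    tps = [
        TimePoint(index=i + 1, block=1, day=1, clock_min=spacing * i,
                  fluids_sampled=frozenset({"P"}))
        for i in range(n_tp)
    ]
    challenges = []
    if challenge and n_tp >= 2:
        challenges = [ChallengeWindow("OGTT", 1, tuple(range(2, n_tp + 1)), 0.0)]
    return StudyDesign(tps, challenges, list(subjects))


def make_catalog(uids, fluid=None, platform="nt-ms"):
    """Catalog entries; fluid parsed from a name.FLUID.platform uid if present."""
    out = []
    for u in uids:
        parts = u.split(".")
        fl = fluid or (parts[1] if len(parts) == 3 and parts[1] in "P U BA BC".split() else "P")
        out.append(MetaboliteInfo(uid=u, display_name=parts[0], fluid=fl, platform=platform))
    return out


def make_dataset(observations, design=None, uids=None, transform_tag="raw"):
    """Build a ProfileDataset from a {(subject, tp, uid): value} mapping."""
    if uids is None:
        uids = sorted({k[2] for k in observations})
    if design is None:
        design = make_design()
    return ProfileDataset.from_observations(
        make_catalog(uids), design, observations, transform_tag
    )


@pytest.fixture
def small_design():
    return make_design()


@pytest.fixture
def two_block_design():
    return build_schedule("humet56")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
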