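import pytest

from musefatigue.pose_io import COCO_JOINTS, Keypoint2D, PoseFrame, ValidityRule
from musefatigue.posture import PostureLabel, PostureParams
from musefatigue.fatigue import FatigueParams
from musefatigue.synthetic import FRAME_H, FRAME_W, figure_for


def make_frame(fig, conf=0.95, frame_index=0, person_id="v", width=FRAME_W, height=FRAME_H):
    """Build a PoseFrame from a {joint: (x, y)} mapping."""
    joints = {name: Keypoint2D(*fig[name], conf) for name in COCO_JOINTS if name in fig}
    return PoseFrame(frame_index, person_id, joints, width, height)


@pytest.fixture
def frame_for():
    def _build(label: PostureLabel, **kwargs) -> PoseFrame:
        return make_frame(figure_for(label), **kwargs)

    return _build


@pytest.fixture
def params():
    return PostureParams()


@pytest.fixture
def rule():
    return ValidityRule()


@pytest.fixture
def fparams():
    return FatigueParams()
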