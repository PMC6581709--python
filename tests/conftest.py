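import numpy as np
import pytest
from shapely.geometry import Point

import handloc as hl


@pytest.fixture(scope="session")
def right_template():
    return hl.default_template("right")


@pytest.fixture(scope="session")
def left_template():
    return hl.default_template("left")


@pytest.fixture(scope="session")
def interior_points(right_template):
    """60 seeded random points strictly inside the default right hand."""
    rng = np.random.default_rng(20240917)
    minx, miny, maxx, maxy = right_template.polygon.bounds
    pts = []
    while len(pts) < 60:
        p = (rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if right_template.polygon.buffer(-0.5).covers(Point(p)):
            pts.append(p)
    return pts


@pytest.fixture(scope="session")
def identity_session(right_template):
    subject = hl.VirtualSubject(field=hl.DistortionField(kind="identity"))
    return hl.simulate_session(subject, right_template, hl.ProtocolConfig(seed=11))
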