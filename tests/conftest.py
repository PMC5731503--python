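import io as _io

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from scafmerge import AssemblyPoint, Orientation
from scafmerge.io import read_orders

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

SCAFFOLDS = [f"s{i}" for i in range(1, 7)]

orientations = st.sampled_from(list(Orientation))
known_orientations = st.sampled_from([Orientation.FORWARD, Orientation.REVERSE])


@st.composite
def points(draw, oriented_only=False):
    """A random well-formed assembly point over a small scaffold universe."""
    s1, s2 = draw(
        st.lists(st.sampled_from(SCAFFOLDS), min_size=2, max_size=2, unique=True)
    )
    strategy = known_orientations if oriented_only else orientations
    return AssemblyPoint(
        scaffold1=s1,
        orientation1=draw(strategy),
        scaffold2=s2,
        orientation2=draw(strategy),
        origin=draw(st.sampled_from(["A1", "A2"])),
        cw=draw(st.one_of(st.none(), st.floats(min_value=0, max_value=1))),
    )


def orders(text, origin):
    return read_orders(_io.StringIO(text), origin)


def group_points(pts):
    """Group random points into assemblies, silencing duplicate collapses."""
    import warnings

    from scafmerge.points import Assembly

    by_origin = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for p in pts:
            by_origin.setdefault(p.origin, Assembly(id=p.origin)).add_point(p)
    return list(by_origin.values())


@pytest.fixture
def fig_assemblies():
    """The three-assembly worked example on scaffolds s1..s4.

    A1 = (+s1 +s3 -s4), (s2); A2 = (+s1 +s2 +s3 s4); A3 = (+s1 +s2 s3), (s4).
    """
    return [
        orders("+s1 +s3 -s4 $\ns2 $\n", "A1"),
        orders("+s1 +s2 +s3 s4 $\n", "A2"),
        orders("+s1 +s2 s3 $\ns4 $\n", "A3"),
    ]
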