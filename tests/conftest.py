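import numpy as np
import pytest

from argsample.arg import (
    Arg,
    COALESCENT,
    RECOMBINATION,
    annotate_ancestral_material,
)
from argsample.substitution import F84, BaseFrequencies


@pytest.fixture
def f84_model():
    return F84(2.0, BaseFrequencies((0.3, 0.2, 0.3, 0.2)))


@pytest.fixture
def two_tip_tree():
    """Minimal valid ARG: two tips coalescing at height 0.3."""
    arg = Arg(10)
    a = arg.add_tip("a")
    b = arg.add_tip("b")
    root = arg.new_node(0.3, COALESCENT)
    Arg.connect(a, 0, root)
    Arg.connect(b, 0, root)
    return annotate_ancestral_material(arg)


@pytest.fixture
def three_tip_recombinant():
    """Hand-built 3-tip ARG, L=10, one recombination on C's branch with
    breakpoint 5: parent 0 (sites < 5) joins (A,B)'s ancestor above,
    parent 1 (sites >= 5) joins A's branch."""
    arg = Arg(10)
    a = arg.add_tip("A")
    b = arg.add_tip("B")
    c = arg.add_tip("C")
    rec = arg.new_node(0.1, RECOMBINATION, breakpoint=5)
    x = arg.new_node(0.15, COALESCENT)     # on A's branch
    coal_ab = arg.new_node(0.2, COALESCENT)
    root = arg.new_node(0.3, COALESCENT)
    Arg.connect(c, 0, rec)
    Arg.connect(a, 0, x)
    Arg.connect(rec, 1, x)                 # right side joins A's branch
    Arg.connect(x, 0, coal_ab)
    Arg.connect(b, 0, coal_ab)
    Arg.connect(coal_ab, 0, root)
    Arg.connect(rec, 0, root)              # left side joins above (A,B)
    return annotate_ancestral_material(arg)


def build_undetectable_arg():
    """4-tip ARG (L=2000) containing all three breakpoint classes:
    a trivial bubble at site 1000 on a's branch, a non-ancestral
    recombination at site 500 on a lineage carrying only [1500, 2000),
    and a detectable recombination at site 1500 on c's branch."""
    arg = Arg(2000)
    a = arg.add_tip("a")
    b = arg.add_tip("b")
    c = arg.add_tip("c")
    d = arg.add_tip("d")
    r3 = arg.new_node(0.003, RECOMBINATION, breakpoint=1000)   # bubble
    c3 = arg.new_node(0.006, COALESCENT)
    coal_ab = arg.new_node(0.010, COALESCENT)
    r1 = arg.new_node(0.015, RECOMBINATION, breakpoint=1500)   # detectable
    r2 = arg.new_node(0.020, RECOMBINATION, breakpoint=500)    # non-ancestral
    c_ed = arg.new_node(0.025, COALESCENT)
    coal_r = arg.new_node(0.030, COALESCENT)
    coal_left = arg.new_node(0.040, COALESCENT)
    root = arg.new_node(0.050, COALESCENT)
    Arg.connect(a, 0, r3)
    Arg.connect(r3, 0, c3)
    Arg.connect(r3, 1, c3)
    Arg.connect(c3, 0, coal_ab)
    Arg.connect(b, 0, coal_ab)
    Arg.connect(c, 0, r1)
    Arg.connect(r1, 1, r2)           # sites >= 1500 up to r2's lineage
    Arg.connect(r2, 0, c_ed)         # empty material side
    Arg.connect(d, 0, c_ed)
    Arg.connect(r2, 1, coal_r)
    Arg.connect(c_ed, 0, coal_r)
    Arg.connect(coal_ab, 0, coal_left)
    Arg.connect(r1, 0, coal_left)
    Arg.connect(coal_r, 0, root)
    Arg.connect(coal_left, 0, root)
    return annotate_ancestral_material(arg)


@pytest.fixture
def undetectable_arg():
    return build_undetectable_arg()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
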