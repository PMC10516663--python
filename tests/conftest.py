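import numpy as np
import pytest

from iresscope.descriptor import (
    HelixElement,
    IresDescriptor,
    LoopElement,
    default_descriptor_6e,
)


@pytest.fixture(scope="session")
def descriptor_6e():
    return default_descriptor_6e()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230710)


@pytest.fixture(scope="session")
def mini_descriptor():
    """A reduced two-helix H-type grammar small enough for exhaustive
    placement enumeration."""
    return IresDescriptor(
        name="mini-pk",
        layout=(
            "P2.1:5", "L2.1a", "P2.2:5", "L2.1b", "P2.1:3", "L2.2", "P2.2:3",
            "codon",
        ),
        helices={
            "P2.1": HelixElement("P2.1", 3, 4),
            "P2.2": HelixElement("P2.2", 3, 4),
        },
        loops={
            "L2.1a": LoopElement("L2.1a", 2, 4),
            "L2.1b": LoopElement("L2.1b", 2, 4),
            "L2.2": LoopElement("L2.2", 2, 5),
        },
        pk_groups={"PKIII": ("P2.1", "P2.2")},
        domains={"2": ("P2.1", "L2.1a", "P2.2", "L2.1b", "L2.2")},
        total_len_range=(21, 45),
        allowed_start_codons=frozenset({"GCU", "ACU"}),
    )
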