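import numpy as np
import pytest

from semmorph.segmentation import BinaryMask, label_instances


def disc_mask(radius: int, pad: int = 4, pixel_size_um: float = 1.0) -> BinaryMask:
    side = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[:side, :side]
    c = radius + pad
    return BinaryMask((yy - c) ** 2 + (xx - c) ** 2 <= radius * radius, pixel_size_um)


def single_cell(mask: BinaryMask):
    cells = label_instances(mask)
    assert len(cells) == 1
    return cells[0]


@pytest.fixture(scope="session")
def rod_field():
    """Small noise-free rod population shared across segmentation/bacteria tests."""
    from semmorph.synthetic import gen_rod_population

    return gen_rod_population(n=12, seed=7)


@pytest.fixture(scope="session")
def three_arm_neuron():
    from semmorph.synthetic import gen_neuron

    return gen_neuron(
        soma_radius_um=6.0,
        arms=[(30.0, 0.0, 0.0), (40.0, 45.0, 0.0), (50.0, 90.0, 0.0)],
        arm_width_um=2.0,
        pixel_size_um=0.2,
        seed=0,
    )
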