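import pytest

from kidneyhist import PhantomConfig, crop_black_border, generate_dataset

#: Small phantoms used by the bin-optimizer tests: big enough to window,
#: small enough that objective evaluations cost microseconds.
SMALL_PHANTOM = PhantomConfig(
    image_size=40, margin_width=4, cyst_radius=6, stone_radius=2,
    tumour_radius=7, n_per_class=2, seed=3,
)


@pytest.fixture(scope="session")
def small_phantom_images():
    """Four-class, two-per-class cropped phantom set for objective/GA tests."""
    return [(lab, crop_black_border(img))
            for lab, img in generate_dataset(SMALL_PHANTOM)]
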