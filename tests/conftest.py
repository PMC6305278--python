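import numpy as np
import pytest

from mpradiomics import CohortSpec, generate_lesion_texture, patches_to_table, quantize


def random_patch(rng: np.random.Generator, shape=(6, 6, 3), ng=4):
    """Random quantized patch with all levels guaranteed representable."""
    from mpradiomics.imaging import QuantizedPatch

    return QuantizedPatch(levels=rng.integers(1, ng + 1, size=shape), ng=ng)


def build_patch_cohort(
    n_per_group: int,
    seed: int,
    blob_scales=(9.0, 5.0, 2.0),
    noise_sd: float = 0.05,
    scale: bool = True,
):
    """Patch-level synthetic cohort feature table (no volume plumbing)."""
    spec = CohortSpec(
        n_per_group=max(n_per_group, 2),
        blob_scale_per_group=blob_scales,
        noise_sd=noise_sd,
        seed=seed,
    )
    pairs, groups = [], []
    for g in (1, 2, 3):
        for i in range(n_per_group):
            rng = np.random.default_rng([seed, g, i])
            t2 = quantize(generate_lesion_texture(g, (21, 21, 3), spec, rng))
            adc = quantize(generate_lesion_texture(g, (21, 21, 3), spec, rng))
            pairs.append((t2, adc))
            groups.append(g)
    return patches_to_table(pairs, groups, scale=scale)


@pytest.fixture(scope="session")
def separable_table():
    """The seeded 30/30/30 cohort with well-separated blob scales (9/5/2)."""
    return build_patch_cohort(n_per_group=30, seed=7)
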