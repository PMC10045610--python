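import numpy as np
import pytest

from lesionnas.synthetic_data import SceneSpec, coco_to_corner, generate_image


def finite_difference_gradcheck(f, params, eps=1e-6, tol=1e-4):
    """Compare analytic gradients of scalar ``f()`` with central differences."""
    for p in params:
        p.grad = None
    f().backward()
    for p in params:
        analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
        numeric = np.zeros_like(p.data)
        it = np.nditer(p.data, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = p.data[i]
            p.data[i] = orig + eps
            hi = f().item()
            p.data[i] = orig - eps
            lo = f().item()
            p.data[i] = orig
            numeric[i] = (hi - lo) / (2 * eps)
        err = np.abs(analytic - numeric).max()
        assert err < tol, f"gradient mismatch {err:.2e} for shape {p.data.shape}"


@pytest.fixture
def rng():
    return np.random.default_rng(0)


TINY_SCENE = SceneSpec(
    image_size=64, lesion_count=(1, 2), lesion_axes=(6.0, 18.0),
    vertebra_width_frac=0.4,
)


def make_detection_dataset(n_images: int, seed: int = 42, scene: SceneSpec = TINY_SCENE):
    """Small (image in [0,1], corner gt boxes) pairs for detector tests."""
    gen = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_images):
        img, boxes = generate_image(scene, gen)
        pairs.append(
            (img.astype(np.float64) / 255.0, [coco_to_corner(b) for b in boxes])
        )
    return pairs


@pytest.fixture(scope="session")
def tiny_dataset():
    return make_detection_dataset(10)
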