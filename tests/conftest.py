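import numpy as np
import pytest

from allofep import (
    BindingSite,
    ResidueKey,
    allosteric_free_energy,
    apply_restraints,
    build_harmonic_model,
    compute_modes,
    hessian,
    make_fixture,
    residue_intensities,
)


def parse_key(text: str) -> ResidueKey:
    """'A:12' / 'A:12B' -> ResidueKey (manifest string form)."""
    chain, _, rest = text.partition(":")
    num = "".join(c for c in rest if c.isdigit() or c == "-")
    return ResidueKey(chain, int(num), rest[len(num):])


@pytest.fixture(scope="session")
def hinge():
    """Two-domain hinge structure with its planted surface-patch site."""
    s, manifest = make_fixture("two_domain_hinge", 60, seed=1)
    site = BindingSite(
        "patch", frozenset(parse_key(k) for k in manifest.planted_site)
    )
    return s, manifest, site


@pytest.fixture(scope="session")
def hinge_profile(hinge):
    """Free/bound Δg profile of the hinge at α=100, 10 modes."""
    s, manifest, site = hinge
    model = build_harmonic_model(s)
    free_modes = compute_modes(hessian(model), n_modes=10)
    bound_modes = compute_modes(
        hessian(apply_restraints(model, [site], alpha=100.0)), n_modes=10
    )
    free_eps = residue_intensities(free_modes, s)
    bound_eps = residue_intensities(bound_modes, s)
    profile = allosteric_free_energy(free_eps, bound_eps)
    return {
        "structure": s,
        "manifest": manifest,
        "site": site,
        "model": model,
        "free_modes": free_modes,
        "bound_modes": bound_modes,
        "free_eps": free_eps,
        "bound_eps": bound_eps,
        "profile": profile,
    }


@pytest.fixture(scope="session")
def dimer():
    s, manifest = make_fixture("symmetric_dimer", 40, seed=3)
    return s, manifest


@pytest.fixture(scope="session")
def globule():
    s, manifest = make_fixture("random_globule", 30, seed=7)
    return s, manifest


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
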