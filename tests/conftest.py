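import numpy as np
import pytest

import cellshapes as cs


def fit_population_2d(pop, body_harmonics=15, nucleus_harmonics=5):
    """Fit body+nucleus Fourier models for a generated population.

    The synthetic nucleus is a 0.4x scaled copy of the body outline, which is
    enough to exercise the two-structure 62+22 feature schema.
    """
    vecs, scalars, conds = [], [], []
    for b, label, doa in pop:
        fb, _ = cs.fit_boundary(b, body_harmonics)
        fn, _ = cs.fit_boundary(cs.Boundary2D(b.points * 0.4),
                                nucleus_harmonics)
        vecs.append(np.concatenate([fb.flatten(), fn.flatten()]))
        scalars.append(doa)
        conds.append(label)
    return vecs, scalars, conds


@pytest.fixture(scope="session")
def circle_boundary():
    """Dense polygonal unit circle (chord error ~1e-8 in area terms)."""
    th = np.linspace(0, 2 * np.pi, 8192, endpoint=False)
    return cs.Boundary2D(np.column_stack([np.cos(th), np.sin(th)]))


@pytest.fixture(scope="session")
def star_boundary():
    """Five-lobed star: r = 10 + 2 cos(5 theta), known harmonic content."""
    th = np.linspace(0, 2 * np.pi, 1024, endpoint=False)
    r = 10.0 + 2.0 * np.cos(5 * th)
    return cs.Boundary2D(np.column_stack([r * np.cos(th), r * np.sin(th)]))


@pytest.fixture(scope="session")
def population_200():
    spec = cs.ShapePopulationSpec(n_cells=200, seed=11)
    return cs.make_boundary_population(spec)


@pytest.fixture(scope="session")
def table_200(population_200):
    """Harmonized 200-cell table (84 coefficients + DOA + one-hot)."""
    vecs, scalars, conds = fit_population_2d(population_200)
    return cs.assemble_table(vecs, scalars, conds, scalar_name="doa")


@pytest.fixture(scope="session")
def trained_model(table_200):
    """One seeded beta-VAE training shared across generative tests."""
    model, history = cs.train_vae(table_200, cs.VAEConfig(epochs=500, seed=5))
    return model, history


@pytest.fixture(scope="session")
def overlap_table():
    """Overlapping-class population: condition classes separable but noisy."""
    spec = cs.ShapePopulationSpec(
        n_cells=120, seed=21, elongation_range=(1.2, 1.8),
        protrusion_amplitude=2.0, noise_sd=0.4, class_spread=0.25)
    pop = cs.make_boundary_population(spec)
    vecs, scalars, conds = [], [], []
    for b, label, doa in pop:
        f, _ = cs.fit_boundary(b, 15)
        vecs.append(f.flatten())
        scalars.append(doa)
        conds.append(label)
    return cs.assemble_table(vecs, scalars, conds, scalar_name="doa")
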