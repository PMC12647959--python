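import numpy as np
import pytest

from holotus import acoustics as ac


@pytest.fixture(scope="session")
def small_array() -> ac.ArrayGeometry:
    """64-element 1 MHz cap: cheap fields for invariant tests."""
    return ac.build_spherical_array(n_elements=64, coverage_deg=150.0,
                                    radius=0.03, frequency=1e6)


@pytest.fixture(scope="session")
def full_array() -> ac.ArrayGeometry:
    """The experimental 512-element, 150-degree, 3 MHz array."""
    return ac.build_spherical_array()


@pytest.fixture(scope="session")
def small_focus_field(small_array) -> ac.ComplexField:
    """Single-focus field of the small array on a coarse grid."""
    holo = ac.make_hologram(small_array, "single")
    grid = ac.Grid.centred((4e-3, 4e-3, 8e-3), 2e-4)
    return ac.synthesize_field(small_array, holo, grid,
                               compute_velocity=True)


def attenuated_plane_wave(alpha: float = 20.0,
                          medium: ac.Medium | None = None,
                          frequency: float = 1e6,
                          n: int = 41, spacing: float = 1e-4,
                          p0: float = 1e5) -> ac.ComplexField:
    """Analytic +z-travelling plane wave in an absorbing medium."""
    if medium is None:
        medium = ac.Medium(density=1000.0, sound_speed=1500.0,
                           attenuation=alpha)
    grid = ac.Grid.centred((spacing * (n - 1),) * 3, spacing)
    omega = 2 * np.pi * frequency
    k = omega / medium.sound_speed
    z = grid.z[None, None, :]
    p = p0 * np.exp((1j * k - medium.attenuation) * z) * np.ones(grid.shape)
    v = np.zeros(grid.shape + (3,), dtype=complex)
    # Euler relation: v_z = p (ik - alpha) / (i omega rho)
    v[..., 2] = p * (1j * k - medium.attenuation) / (1j * omega
                                                     * medium.density)
    return ac.ComplexField(grid=grid, pressure=p, medium=medium,
                           frequency=frequency, velocity=v)
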