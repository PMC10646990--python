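import numpy as np
import pytest

from stackmap.synthetic_data import synth_reference_config


@pytest.fixture(scope="session")
def reference_box():
    """The solvated two-stack reference box (built once per session)."""
    return synth_reference_config(seed=1)


def py_hard_sphere_sq(q_sigma, phi):
    """Analytic Percus–Yevick hard-sphere structure factor (test oracle).

    Direct implementation of the Ashcroft–Lekner closed form for the
    direct correlation function; independent of the package's
    Ornstein–Zernike solver.
    """
    u = np.asarray(q_sigma, dtype=float)
    a = (1 + 2 * phi) ** 2 / (1 - phi) ** 4
    b = -6 * phi * (1 + phi / 2) ** 2 / (1 - phi) ** 4
    g = phi * a / 2
    nc = -24 * phi * (
        a * (np.sin(u) - u * np.cos(u)) / u**3
        + b * (2 * u * np.sin(u) - (u**2 - 2) * np.cos(u) - 2) / u**4
        + g * ((4 * u**3 - 24 * u) * np.sin(u) - (u**4 - 12 * u**2 + 24) * np.cos(u) + 24) / u**6
    )
    return 1.0 / (1.0 - nc)


def brute_force_rdf(frames, pair, bin_width, r_max):
    """O(N²) double-loop RDF oracle with the same binning convention."""
    alpha, beta = pair
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    g = np.zeros_like(r_mid)
    for frame in frames:
        box = frame.box_side
        pos_a = frame.select(alpha)
        pos_b = frame.select(beta)
        counts = np.zeros_like(r_mid)
        same = alpha == beta
        for i in range(len(pos_a)):
            for j in range(len(pos_b)):
                if same and i == j:
                    continue
                d = pos_a[i] - pos_b[j]
                d = d - box * np.round(d / box)
                rr = float(np.sqrt(d @ d))
                k = int(rr / bin_width)
                if k < len(counts):
                    counts[k] += 1
        rho_b = (len(pos_b) - (1 if same else 0)) / box**3
        g += counts / (len(pos_a) * rho_b * 4 * np.pi * r_mid**2 * bin_width)
    return r_mid, g / len(frames)
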