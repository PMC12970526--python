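"""Synthetic GUV phantoms with known ground truth.

Two generators emulate the two acquisition modes of the real experiment:

``simulate_spectral_stack``
    A lambda-scan confocal image of a single GUV equatorial section: a thin
    membrane ring whose per-pixel emission spectrum is a smooth two-band
    profile tuned so that the generalized polarization computed from the two
    analysis channels equals a prescribed ``gp_true``.  The ring brightness is
    modulated around the circle by a cos^2 photoselection term (linearly
    polarized excitation excites fluorophores aligned with the polarization
    axis more efficiently), and photon counts are drawn as independent
    Poisson variates.

``simulate_decay``
    A TCSPC histogram over one laser repetition period: a multi-exponential
    decay convolved with a Gaussian instrument response function (IRF),
    periodically wrapped, with a uniform background floor, scaled to a photon
    budget, then Poisson sampled.

Both are deterministic given ``(spec, seed)``; ``simulate_condition_batch``
turns the per-condition summary statistics of an experiment (mean, SD, n)
into a batch of per-vesicle phantom specs for recovery studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .spectral_gp import SpectralStack, nearest_channel

DEFAULT_CHANNEL_CENTERS = tuple(float(c) for c in range(565, 700, 10))
"""14 emission channels: 10 nm bands spanning 560-700 nm."""

# Two-band spectral model for the membrane probe: emission is a mixture of a
# blue band (ordered/packed environment) and a red band (disordered), and the
# mixture weight is what encodes the generalized polarization.
BAND_BLUE_NM = 580.0
BAND_RED_NM = 635.0
BAND_SIGMA_NM = 35.0

DEFAULT_BLUE_NM = 570.0
DEFAULT_RED_NM = 640.0

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.355


def child_seed(seed: int, index: int) -> int:
    """Counter-based per-item seed: order-independent and below 2**31."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class GuvGeometry:
    """Circular membrane ring of one GUV in a square field of view.

    ``ring_width`` is the full width of the membrane annulus (the radial
    intensity profile is Gaussian with sigma = ring_width / 2.355, i.e. the
    annulus width is read as a FWHM, matching a diffraction-limited membrane
    cross section).
    """

    center: tuple[float, float] = (128.0, 128.0)  # (x, y) in px
    radius: float = 60.0
    ring_width: float = 4.0
    image_size: tuple[int, int] = (256, 256)  # (rows, cols)

    def __post_init__(self) -> None:
        if not (self.radius > self.ring_width / 2.0 > 0.0):
            raise ValueError("require radius > ring_width/2 > 0")
        x, y = self.center
        reach = self.radius + self.ring_width / 2.0
        h, w = self.image_size
        if not (reach <= x <= w - 1 - reach and reach <= y <= h - 1 - reach):
            raise ValueError("ring extends outside the image bounds")


@dataclass(frozen=True)
class SpectralPhantomSpec:
    """Parameters of one synthetic spectral GUV stack."""

    gp_true: float
    geometry: GuvGeometry = field(default_factory=GuvGeometry)
    total_photons_per_pixel: float = 1000.0
    photoselection_depth: float = 0.6
    polarization_axis_deg: float = 0.0
    background_rate: float = 2.0  # expected counts per pixel, summed over channels
    channel_centers: tuple[float, ...] = DEFAULT_CHANNEL_CENTERS
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.gp_true <= 1.0:
            raise ValueError("gp_true must lie in [-1, 1]")
        if abs(self.gp_true) == 1.0:
            # the band intensity ratio (1+g)/(1-g) is 0 or infinite: the
            # two-band emission model cannot represent it with finite counts
            raise ValueError("gp_true = +/-1 is not representable (band ratio undefined)")
        if not 0.0 <= self.photoselection_depth <= 1.0:
            raise ValueError("photoselection_depth must lie in [0, 1]")
        if self.total_photons_per_pixel < 0 or self.background_rate < 0:
            raise ValueError("expected counts must be nonnegative")
        cc = np.asarray(self.channel_centers, dtype=float)
        if cc.ndim != 1 or cc.size < 2 or not np.all(np.diff(cc) > 0):
            raise ValueError("channel_centers must be strictly increasing")
        # fail early if gp_true falls outside what the two-band spectrum spans
        _band_weight(self.gp_true, cc)


@dataclass(frozen=True)
class DecayPhantomSpec:
    """Parameters of one synthetic TCSPC decay histogram."""

    component_fractions: tuple[float, ...]  # photon (intensity) fractions, sum to 1
    component_lifetimes: tuple[float, ...]  # ns
    rep_period: float = 50.0  # ns (20 MHz repetition)
    irf_center: float = 2.0  # ns
    irf_fwhm: float = 0.2  # ns
    n_bins: int = 256
    photon_budget: float = 1e5
    background_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.component_fractions, dtype=float)
        tau = np.asarray(self.component_lifetimes, dtype=float)
        if f.shape != tau.shape or f.ndim != 1 or f.size == 0:
            raise ValueError("fractions and lifetimes must be 1-d and the same length")
        if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("component fractions must be >= 0 and sum to 1")
        if np.any(tau <= 0):
            raise ValueError("lifetimes must be positive")
        if self.rep_period <= 0:
            raise ValueError("rep_period must be positive")
        if self.n_bins < 4:
            raise ValueError("need at least 4 time bins")
        if self.photon_budget < 0:
            raise ValueError("photon_budget must be nonnegative")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must lie in [0, 1]")
        if np.any(tau >= 10.0 * self.rep_period):
            warnings.warn(
                "component lifetime >= 10x the repetition period: the decay tail "
                "cannot be resolved within one period",
                stacklevel=2,
            )

    @property
    def tau_m_int_true(self) -> float:
        """True intensity-weighted mean lifetime, sum(I_k tau_k) / sum(I_k)."""
        f = np.asarray(self.component_fractions, dtype=float)
        tau = np.asarray(self.component_lifetimes, dtype=float)
        return float(np.sum(f * tau) / np.sum(f))


@dataclass(frozen=True)
class PhantomGroundTruth:
    """True parameters behind one phantom, for recovery tests."""

    spec: object
    true_value: float  # gp_true or tau_m_int, depending on modality
    membrane_mask: np.ndarray | None = None  # geometric annulus, spectral phantoms only
    seed: int = 0


# ---------------------------------------------------------------------------
# spectral phantom
# ---------------------------------------------------------------------------


def _band_profiles(channels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    b = np.exp(-((channels - BAND_BLUE_NM) ** 2) / (2.0 * BAND_SIGMA_NM**2))
    r = np.exp(-((channels - BAND_RED_NM) ** 2) / (2.0 * BAND_SIGMA_NM**2))
    return b, r


def _band_weight(gp: float, channels: np.ndarray) -> float:
    """Mixture weight of the blue band so the channel ratio encodes ``gp``.

    Solves I_blue_channel / I_red_channel = (1+gp)/(1-gp) for the weight w of
    the blue emission band in the two-band mixture; the two analysis channels
    are the ones nearest 570 and 640 nm (ties to the shorter wavelength).
    """
    channels = np.asarray(channels, dtype=float)
    i_b = nearest_channel(channels, DEFAULT_BLUE_NM)
    i_r = nearest_channel(channels, DEFAULT_RED_NM)
    ratio = (1.0 + gp) / (1.0 - gp)
    blue, red = _band_profiles(channels)
    num = ratio * red[i_r] - red[i_b]
    den = (blue[i_b] - red[i_b]) - ratio * (blue[i_r] - red[i_r])
    w = num / den
    if not 0.0 <= w <= 1.0:
        lo, hi = gp_representable_range(channels)
        raise ValueError(
            f"gp_true={gp:.3f} outside the range representable by the two-band "
            f"spectral model ([{lo:.3f}, {hi:.3f}])"
        )
    return float(w)


def gp_representable_range(channels=DEFAULT_CHANNEL_CENTERS) -> tuple[float, float]:
    """GP interval the two-band emission model can encode on this channel grid."""
    channels = np.asarray(channels, dtype=float)
    i_b = nearest_channel(channels, DEFAULT_BLUE_NM)
    i_r = nearest_channel(channels, DEFAULT_RED_NM)
    blue, red = _band_profiles(channels)
    r_lo = red[i_b] / red[i_r]  # pure red band
    r_hi = blue[i_b] / blue[i_r]  # pure blue band
    return (r_lo - 1.0) / (r_lo + 1.0), (r_hi - 1.0) / (r_hi + 1.0)


def expected_spectral_cube(spec: SpectralPhantomSpec) -> np.ndarray:
    """Noise-free expected photon-count cube (channels x rows x cols)."""
    geom = spec.geometry
    channels = np.asarray(spec.channel_centers, dtype=float)
    h, w = geom.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = geom.center
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    sigma_r = geom.ring_width * FWHM_TO_SIGMA
    radial = np.exp(-((r - geom.radius) ** 2) / (2.0 * sigma_r**2))
    axis = np.deg2rad(spec.polarization_axis_deg)
    depth = spec.photoselection_depth
    modulation = (1.0 - depth) + depth * np.cos(theta - axis) ** 2
    profile = radial * modulation
    peak = profile.max()
    if peak > 0:
        profile = profile / peak

    wgt = _band_weight(spec.gp_true, channels)
    blue, red = _band_profiles(channels)
    spectrum = wgt * blue + (1.0 - wgt) * red
    spectrum = spectrum / spectrum.sum()  # fraction of membrane photons per channel

    cube = spec.total_photons_per_pixel * profile[None] * spectrum[:, None, None]
    cube += spec.background_rate / channels.size
    return cube


def true_membrane_mask(geom: GuvGeometry) -> np.ndarray:
    """Geometric annulus |r - radius| <= ring_width/2 (pixel centers)."""
    h, w = geom.image_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cx, cy = geom.center
    r = np.hypot(xx - cx, yy - cy)
    return np.abs(r - geom.radius) <= geom.ring_width / 2.0


def simulate_spectral_stack(
    spec: SpectralPhantomSpec,
) -> tuple[SpectralStack, PhantomGroundTruth]:
    """Draw one Poisson-noisy spectral GUV stack. Deterministic given spec.seed."""
    expected = expected_spectral_cube(spec)
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(expected).astype(np.int64)
    stack = SpectralStack(
        data=counts,
        channel_centers=np.asarray(spec.channel_centers, dtype=float),
        meta={"phantom_seed": spec.seed, "gp_true": spec.gp_true},
    )
    truth = PhantomGroundTruth(
        spec=spec,
        true_value=spec.gp_true,
        membrane_mask=true_membrane_mask(spec.geometry),
        seed=spec.seed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# decay phantom
# ---------------------------------------------------------------------------

N_WRAP_PERIODS = 3  # preceding excitation pulses summed into the window


def _component_bin_masses(
    edges: np.ndarray, tau: float, mu: float, sigma: float, period: float
) -> np.ndarray:
    """Exact bin masses of a Gaussian-IRF-convolved exponential, wrapped.

    The convolution of exp(-t/tau)/tau with a Gaussian N(mu, sigma^2) is the
    exponentially modified Gaussian; its CDF gives exact bin integrals.  The
    periodic wrap adds the tails of the ``N_WRAP_PERIODS`` preceding pulses.
    """
    dist = stats.exponnorm(K=tau / sigma, loc=mu, scale=sigma)
    mass = np.zeros(edges.size - 1)
    for j in range(N_WRAP_PERIODS + 1):
        cdf = dist.cdf(edges + j * period)
        mass += np.diff(cdf)
    return mass


def expected_decay(spec: DecayPhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free expected histogram; returns (bin_edges, expected_counts, irf_counts)."""
    edges = np.linspace(0.0, spec.rep_period, spec.n_bins + 1)
    sigma = max(spec.irf_fwhm * FWHM_TO_SIGMA, 1e-6)
    signal = np.zeros(spec.n_bins)
    for f, tau in zip(spec.component_fractions, spec.component_lifetimes):
        mass = _component_bin_masses(edges, tau, spec.irf_center, sigma, spec.rep_period)
        signal += f * mass / mass.sum()
    expected = spec.photon_budget * (
        (1.0 - spec.background_fraction) * signal
        + spec.background_fraction / spec.n_bins
    )
    irf = np.diff(stats.norm.cdf(edges, loc=spec.irf_center, scale=sigma))
    irf = irf / irf.sum() * 1e5  # noise-free reference IRF, arbitrary total
    return edges, expected, irf


def simulate_decay(spec: DecayPhantomSpec):
    """Draw one Poisson-noisy TCSPC histogram. Deterministic given spec.seed.

    Returns ``(DecayHistogram, PhantomGroundTruth)``; the ground-truth value
    is the true intensity-weighted mean lifetime.
    """
    from .flim import DecayHistogram  # local import to avoid a cycle

    edges, expected, irf = expected_decay(spec)
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(expected).astype(np.int64)
    hist = DecayHistogram(
        bin_edges=edges, counts=counts, irf_counts=irf, rep_period=spec.rep_period
    )
    truth = PhantomGroundTruth(spec=spec, true_value=spec.tau_m_int_true, seed=spec.seed)
    return hist, truth


# ---------------------------------------------------------------------------
# condition batches and two-domain vesicles
# ---------------------------------------------------------------------------

# Biexponential composition used when a batch is parametrized only by its
# target intensity-weighted mean lifetime: a short component carrying 25% of
# the photons at tau_m/2 and a long component carrying 75% at 7*tau_m/6, so
# that 0.25*(tau_m/2) + 0.75*(7*tau_m/6) = tau_m exactly.
LIFETIME_FRACTIONS = (0.25, 0.75)


def biexponential_for_tau_m(tau_m: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Component (fractions, lifetimes) whose intensity-weighted mean is ``tau_m``."""
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    return LIFETIME_FRACTIONS, (tau_m / 2.0, 7.0 * tau_m / 6.0)


def _random_geometry(rng: np.random.Generator, image_size=(256, 256)) -> GuvGeometry:
    h, w = image_size
    r_hi = min(h, w) / 2.0 - 15.0
    radius = float(rng.uniform(min(40.0, 0.5 * r_hi), min(80.0, r_hi)))
    cx = w / 2.0 + float(rng.uniform(-10.0, 10.0))
    cy = h / 2.0 + float(rng.uniform(-10.0, 10.0))
    return GuvGeometry(center=(cx, cy), radius=radius, ring_width=4.0, image_size=image_size)


def simulate_condition_batch(
    n_vesicles: int,
    readout_mean: float,
    readout_sd: float,
    modality: str,
    seed: int,
    **spec_overrides,
) -> tuple[list, list[float]]:
    """Per-vesicle phantom specs for one experimental condition.

    True per-vesicle readouts are drawn from Normal(mean, sd); GP values are
    clamped to the representable range of the spectral model and lifetimes to
    a small positive floor.  Returns ``(specs, true_values)``.
    """
    if n_vesicles < 1:
        raise ValueError("n_vesicles must be >= 1")
    if readout_sd < 0:
        raise ValueError("readout_sd must be >= 0")
    if modality not in ("GP", "lifetime"):
        raise ValueError("modality must be 'GP' or 'lifetime'")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    truths = rng.normal(readout_mean, readout_sd, size=n_vesicles)
    specs = []
    if modality == "GP":
        image_size = spec_overrides.pop("image_size", (256, 256))
        lo, hi = gp_representable_range(
            spec_overrides.get("channel_centers", DEFAULT_CHANNEL_CENTERS)
        )
        eps = 1e-3
        truths = np.clip(truths, lo + eps, hi - eps)
        for i, g in enumerate(truths):
            s = child_seed(seed, i + 1)
            geom_rng = np.random.default_rng(np.random.SeedSequence([int(seed), i + 1, 1]))
            specs.append(
                SpectralPhantomSpec(
                    gp_true=float(g),
                    geometry=_random_geometry(geom_rng, image_size),
                    seed=s,
                    **spec_overrides,
                )
            )
    else:
        truths = np.clip(truths, 0.1, None)
        for i, tau_m in enumerate(truths):
            s = child_seed(seed, i + 1)
            fr, taus = biexponential_for_tau_m(float(tau_m))
            specs.append(
                DecayPhantomSpec(
                    component_fractions=fr,
                    component_lifetimes=taus,
                    seed=s,
                    **spec_overrides,
                )
            )
    return specs, [float(t) for t in truths]


@dataclass(frozen=True)
class TwoDomainPhantom:
    """Per-pixel decays from a phase-separated vesicle with two lifetime domains."""

    counts: np.ndarray  # (n_pixels, n_bins)
    bin_edges: np.ndarray
    irf_counts: np.ndarray
    rep_period: float
    labels: np.ndarray  # 0 = disordered (short tau), 1 = ordered (long tau)
    tau_ordered: float
    tau_disordered: float


def simulate_two_domain_vesicle(
    tau_ordered: float,
    tau_disordered: float,
    n_pixels_per_domain: int = 150,
    photons_per_pixel: float = 5000.0,
    n_bins: int = 256,
    rep_period: float = 50.0,
    seed: int = 0,
) -> TwoDomainPhantom:
    """Pixels from a vesicle with coexisting ordered/disordered membrane domains.

    Each pixel emits a monoexponential decay at its domain's lifetime
    (IRF-convolved, wrapped, Poisson sampled), mimicking the domain-resolved
    lifetime contrast seen in phase-separated GUVs.
    """
    if tau_ordered <= tau_disordered:
        raise ValueError("expected tau_ordered > tau_disordered")
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    edges = irf = None
    for label, tau in ((0, tau_disordered), (1, tau_ordered)):
        spec = DecayPhantomSpec(
            component_fractions=(1.0,),
            component_lifetimes=(tau,),
            n_bins=n_bins,
            rep_period=rep_period,
            photon_budget=photons_per_pixel,
            seed=0,
        )
        edges, expected, irf = expected_decay(spec)
        draws = rng.poisson(expected[None, :].repeat(n_pixels_per_domain, axis=0))
        rows.append(draws)
        labels.extend([label] * n_pixels_per_domain)
    return TwoDomainPhantom(
        counts=np.vstack(rows).astype(np.int64),
        bin_edges=edges,
        irf_counts=irf,
        rep_period=rep_period,
        labels=np.asarray(labels),
        tau_ordered=tau_ordered,
        tau_disordered=tau_disordered,
    )
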