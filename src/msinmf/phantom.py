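"""Synthetic tissue phantoms and raster-acquisition / serum simulators.

Everything downstream (cube construction, factorization, clustering,
annotation, classification) is exercised against data produced here, so the
generators are deterministic pure functions of (spec, seed) and every noise
source is explicit: multiplicative per-pixel lognormal gain, additive
Poisson-count background peaks uniform in m/z, Gaussian m/z jitter scaling
linearly with m/z, and the 35Cl/37Cl M+2 isotope doublet for single-chlorine
species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ProfilePeak",
    "RegionDef",
    "PhantomSpec",
    "ScanEvent",
    "ScanStream",
    "StageTrack",
    "AcquisitionParams",
    "SerumFeature",
    "SerumSpec",
    "make_phantom",
    "simulate_acquisition",
    "simulate_serum",
    "default_phantom_spec",
    "default_serum_spec",
]

#: 37Cl - 35Cl mass spacing (Th) and isotopic intensity ratio M+2 / M for
#: one chlorine atom (abundances 24.22 / 75.77 -> ~3:1 pattern).
CL_M2_SPACING = 1.99705
CL_M2_RATIO = 0.3196


class PhantomError(ValueError):
    """Raised for invalid phantom specifications."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfilePeak:
    """One species in a region profile.

    ``rel_intensity`` is relative to the region base peak (exactly one peak
    per profile has 1.0); ``n_chlorine == 1`` species are emitted together
    with their M+2 isotopologue.
    """

    mz: float
    rel_intensity: float
    n_chlorine: int = 0


@dataclass(frozen=True)
class RegionDef:
    """A named tissue region: an ellipse or rectangle in micrometres.

    ``geometry`` is ``("ellipse", cx, cy, a, b)`` (center and semi-axes) or
    ``("rect", x0, y0, x1, y1)``.
    """

    name: str
    geometry: tuple
    profile_id: str


@dataclass(frozen=True)
class PhantomSpec:
    width_um: float
    height_um: float
    pixel_pitch_um: float
    regions: tuple[RegionDef, ...]
    profiles: Mapping[str, tuple[ProfilePeak, ...]]
    pixel_gain_sigma: float = 0.0
    mz_jitter_sigma_at_ref: float = 0.0   # Th at the reference m/z below
    jitter_ref_mz: float = 850.0
    background_peak_rate: float = 0.0     # expected background peaks per scan
    base_intensity: float = 1000.0        # counts for a rel_intensity-1.0 peak
    seed: int = 0

    def validate(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0 or self.pixel_pitch_um <= 0:
            raise PhantomError("frame dimensions and pixel pitch must be positive")
        for dim, name in ((self.width_um, "width"), (self.height_um, "height")):
            if abs(dim / self.pixel_pitch_um - round(dim / self.pixel_pitch_um)) > 1e-9:
                raise PhantomError(f"pixel pitch must divide the frame {name}")
        if self.pixel_gain_sigma < 0 or self.background_peak_rate < 0:
            raise PhantomError("noise parameters must be non-negative")
        for region in self.regions:
            if region.profile_id not in self.profiles:
                raise PhantomError(f"region {region.name!r} references unknown profile "
                                   f"{region.profile_id!r}")
            self._check_geometry(region)
        for pid, peaks in self.profiles.items():
            if not peaks:
                raise PhantomError(f"profile {pid!r} is empty")
            rels = [p.rel_intensity for p in peaks]
            if any(not (0 < r <= 1) for r in rels):
                raise PhantomError(f"profile {pid!r}: rel_intensity must be in (0, 1]")
            if sum(1 for r in rels if r == 1.0) != 1:
                raise PhantomError(f"profile {pid!r} must have exactly one base peak "
                                   "(rel_intensity == 1)")
            if any(p.n_chlorine < 0 for p in peaks):
                raise PhantomError(f"profile {pid!r}: n_chlorine must be >= 0")

    def _check_geometry(self, region: RegionDef) -> None:
        kind = region.geometry[0]
        if kind == "ellipse":
            _, cx, cy, a, b = region.geometry
            if not (0 <= cx - a and cx + a <= self.width_um
                    and 0 <= cy - b and cy + b <= self.height_um):
                raise PhantomError(f"region {region.name!r} extends outside the frame")
        elif kind == "rect":
            _, x0, y0, x1, y1 = region.geometry
            if not (0 <= x0 < x1 <= self.width_um and 0 <= y0 < y1 <= self.height_um):
                raise PhantomError(f"region {region.name!r} extends outside the frame")
        else:
            raise PhantomError(f"unknown geometry kind {kind!r} in region {region.name!r}")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (int(round(self.height_um / self.pixel_pitch_um)),
                int(round(self.width_um / self.pixel_pitch_um)))


# ---------------------------------------------------------------------------
# acquisition record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanEvent:
    """One centroided mass scan: strictly increasing m/z, intensities >= 0."""

    time_s: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("m/z and intensity lists must have equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing within a scan")
        if inten.size and inten.min() < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)


@dataclass(frozen=True)
class ScanStream:
    """Time-ordered container of scans."""

    scans: tuple[ScanEvent, ...]

    def __len__(self) -> int:
        return len(self.scans)

    def __iter__(self):
        return iter(self.scans)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time_s for s in self.scans])


@dataclass(frozen=True)
class StageTrack:
    """Stage position log: (time_s, x_um, y_um) samples plus raster metadata.

    ``pass_windows`` lists (line_index, t_start, t_end) for the first pass
    along each raster line; only scans inside these windows image the sample.
    """

    samples: np.ndarray           # (n, 3): time_s, x_um, y_um
    velocity_x_um_s: float
    line_step_um: float
    pass_windows: tuple[tuple[int, float, float], ...]

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[1] != 3:
            raise ValueError("track samples must be (n, 3): time, x, y")
        if np.any(np.diff(samples[:, 0]) <= 0):
            raise ValueError("track times must be strictly increasing")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class AcquisitionParams:
    """Raster kinematics: stage speed, line step, and the scan period."""

    velocity_x_um_s: float = 160.0
    line_step_um: float = 200.0
    scan_period_s: float = 1.25


# ---------------------------------------------------------------------------
# phantom rasterization
# ---------------------------------------------------------------------------

def _region_mask(region: RegionDef, spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.grid_shape
    pitch = spec.pixel_pitch_um
    x = (np.arange(cols) + 0.5) * pitch
    y = (np.arange(rows) + 0.5) * pitch
    xx, yy = np.meshgrid(x, y)
    kind = region.geometry[0]
    if kind == "ellipse":
        _, cx, cy, a, b = region.geometry
        return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    _, x0, y0, x1, y1 = region.geometry
    return (xx >= x0) & (xx < x1) & (yy >= y0) & (yy < y1)


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, dict[int, tuple[ProfilePeak, ...]]]:
    """Rasterize the region map.

    Returns the label image (0 = off-tissue background, regions labelled
    1..n in spec order) and a label -> profile-peaks mapping.  Overlapping
    regions with different profiles are rejected by name.
    """
    spec.validate()
    rows, cols = spec.grid_shape
    labels = np.zeros((rows, cols), dtype=int)
    profiles: dict[int, tuple[ProfilePeak, ...]] = {}
    for i, region in enumerate(spec.regions, start=1):
        mask = _region_mask(region, spec)
        clash = mask & (labels > 0)
        if clash.any():
            for j in np.unique(labels[clash]):
                other = spec.regions[j - 1]
                if other.profile_id != region.profile_id:
                    raise PhantomError(
                        f"regions {other.name!r} and {region.name!r} overlap "
                        "but carry different profiles"
                    )
            mask = mask & (labels == 0)  # same profile: first region keeps the pixels
        labels[mask] = i
        profiles[i] = tuple(spec.profiles[region.profile_id])
    return labels, profiles


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------

def simulate_acquisition(
    label_image: np.ndarray,
    profiles: Mapping[int, Sequence[ProfilePeak]],
    spec: PhantomSpec,
    acq: AcquisitionParams | None = None,
) -> tuple[ScanStream, StageTrack]:
    """Simulate a comb-raster acquisition over the phantom.

    The stage traverses each pixel row left-to-right at constant speed
    (first pass), with instantaneous flyback modelled as a one-scan-period
    settle gap before the next line; no scans are emitted during flyback.
    Scans fire every ``scan_period_s`` starting half a period into each
    line, so with ``scan_period = pitch / velocity`` each scan lands exactly
    on a pixel center.
    """
    acq = acq or AcquisitionParams()
    if acq.scan_period_s <= 0 or acq.velocity_x_um_s <= 0:
        raise PhantomError("scan period and velocity must be positive")
    if not math.isclose(acq.line_step_um, spec.pixel_pitch_um, rel_tol=1e-9):
        raise PhantomError(
            f"line step ({acq.line_step_um} um) must equal the phantom pixel "
            f"pitch ({spec.pixel_pitch_um} um) so raster lines sample pixel rows"
        )
    rows, cols = label_image.shape
    width = cols * spec.pixel_pitch_um
    traverse_s = width / acq.velocity_x_um_s
    n_per_line = int(math.floor(traverse_s / acq.scan_period_s))
    if n_per_line == 0:
        raise PhantomError(
            f"scan period {acq.scan_period_s}s exceeds the line traverse time "
            f"{traverse_s:.3f}s; no line would receive a scan"
        )
    rng = np.random.default_rng(spec.seed)
    sigma_rel = spec.mz_jitter_sigma_at_ref / spec.jitter_ref_mz
    mz_lo, mz_hi = 400.0, 1000.0

    scans: list[ScanEvent] = []
    track_samples: list[tuple[float, float, float]] = []
    windows: list[tuple[int, float, float]] = []
    settle = acq.scan_period_s
    t_line = 0.0
    for line in range(rows):
        y = (line + 0.5) * spec.pixel_pitch_um
        t0, t1 = t_line, t_line + traverse_s
        track_samples.append((t0, 0.0, y))
        track_samples.append((t1, width, y))
        windows.append((line, t0, t1))
        for i in range(n_per_line):
            t = t0 + (i + 0.5) * acq.scan_period_s
            x = (t - t0) * acq.velocity_x_um_s
            col = min(int(x / spec.pixel_pitch_um), cols - 1)
            label = int(label_image[line, col])
            mzs: list[float] = []
            intens: list[float] = []
            if label > 0:
                gain = math.exp(rng.normal(0.0, spec.pixel_gain_sigma)) \
                    if spec.pixel_gain_sigma > 0 else 1.0
                for peak in profiles[label]:
                    inten = spec.base_intensity * peak.rel_intensity * gain
                    mzs.append(peak.mz + (rng.normal(0.0, sigma_rel * peak.mz)
                                          if sigma_rel > 0 else 0.0))
                    intens.append(inten)
                    if peak.n_chlorine == 1:
                        m2 = peak.mz + CL_M2_SPACING
                        mzs.append(m2 + (rng.normal(0.0, sigma_rel * m2)
                                         if sigma_rel > 0 else 0.0))
                        intens.append(inten * CL_M2_RATIO)
            if spec.background_peak_rate > 0:
                n_bg = rng.poisson(spec.background_peak_rate)
                for _ in range(n_bg):
                    mzs.append(rng.uniform(mz_lo, mz_hi))
                    intens.append(rng.exponential(0.02 * spec.base_intensity))
            mz_arr = np.asarray(mzs)
            int_arr = np.asarray(intens)
            order = np.argsort(mz_arr, kind="stable")
            mz_arr, int_arr = mz_arr[order], int_arr[order]
            # merge exact m/z ties so scans stay strictly increasing
            if mz_arr.size > 1 and np.any(np.diff(mz_arr) == 0):
                uniq, inv = np.unique(mz_arr, return_inverse=True)
                merged = np.zeros_like(uniq)
                np.add.at(merged, inv, int_arr)
                mz_arr, int_arr = uniq, merged
            scans.append(ScanEvent(time_s=t, mz=mz_arr, intensity=int_arr))
        t_line = t1 + settle
    track = StageTrack(
        samples=np.asarray(track_samples),
        velocity_x_um_s=acq.velocity_x_um_s,
        line_step_um=acq.line_step_um,
        pass_windows=tuple(windows),
    )
    return ScanStream(tuple(scans)), track


# ---------------------------------------------------------------------------
# serum simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SerumFeature:
    feature_id: str
    log2_fold_change: float
    base_abundance: float = 1000.0
    lognormal_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be positive")
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be positive")


@dataclass(frozen=True)
class SerumSpec:
    """Design of a synthetic case/control serum feature matrix."""

    n_case: int
    n_control: int
    features: tuple[SerumFeature, ...]
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per class")
        if not self.features:
            raise ValueError("need at least one feature")


def simulate_serum(spec: SerumSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw a samples x features abundance matrix and class labels.

    Case abundances are lognormal with log-mean ``log(base) + log2fc*log 2``;
    controls use ``log(base)``.  Labels are ``"ET"`` (case, first rows) and
    ``"control"``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_case + spec.n_control
    X = np.empty((n, len(spec.features)))
    for j, feat in enumerate(spec.features):
        mu = math.log(feat.base_abundance)
        X[: spec.n_case, j] = rng.lognormal(
            mu + feat.log2_fold_change * math.log(2.0), feat.lognormal_sigma, spec.n_case
        )
        X[spec.n_case:, j] = rng.lognormal(mu, feat.lognormal_sigma, spec.n_control)
    labels = np.array(["ET"] * spec.n_case + ["control"] * spec.n_control)
    return X, labels


# ---------------------------------------------------------------------------
# defaults mirroring the studied anatomy
# ---------------------------------------------------------------------------

# Region profiles: healthy tissue dominated by the PI(38:4) [M-H]- peak at
# m/z 885.5499; the tumor and blood-filled cyst carry the annotated ceramide,
# sphingomyelin, lysophospholipid, cholesterol-sulfate and bilirubin ions,
# with chloride adducts flagged for M+2 emission.
_OVARY = (
    ProfilePeak(885.5499, 1.0),
    ProfilePeak(465.3044, 0.30),
    ProfilePeak(909.5489, 0.50),
    ProfilePeak(833.5120, 0.15),
)
_UTERUS = (
    ProfilePeak(885.5499, 1.0),
    ProfilePeak(766.5324, 0.55),
    ProfilePeak(788.5369, 0.45),
    ProfilePeak(716.5247, 0.35),
    ProfilePeak(747.5108, 0.25),
)
_TUMOR = (
    ProfilePeak(572.4815, 1.0, n_chlorine=1),
    ProfilePeak(682.5911, 0.80, n_chlorine=1),
    ProfilePeak(684.6067, 0.65, n_chlorine=1),
    ProfilePeak(536.5048, 0.40),
    ProfilePeak(583.2562, 0.30),
    ProfilePeak(885.5499, 0.35),
    ProfilePeak(465.3044, 0.30),
    ProfilePeak(524.2994, 0.20),
    ProfilePeak(599.3202, 0.25),
    ProfilePeak(737.5370, 0.20, n_chlorine=1),
    ProfilePeak(847.6465, 0.15, n_chlorine=1),
    ProfilePeak(656.5754, 0.12, n_chlorine=1),
    ProfilePeak(658.5910, 0.10, n_chlorine=1),
    ProfilePeak(626.5285, 0.08, n_chlorine=1),
    ProfilePeak(646.6144, 0.15),
    ProfilePeak(648.6300, 0.12),
    ProfilePeak(436.2834, 0.10),
    ProfilePeak(480.3096, 0.10),
    ProfilePeak(464.3147, 0.08),
)
_CYST = (
    ProfilePeak(583.2562, 1.0),
    ProfilePeak(572.4815, 0.60, n_chlorine=1),
    ProfilePeak(682.5911, 0.40, n_chlorine=1),
    ProfilePeak(885.5499, 0.10),
)


def default_phantom_spec(
    seed: int = 0,
    pixel_pitch_um: float = 200.0,
    pixel_gain_sigma: float = 0.2,
    mz_jitter_sigma_at_ref: float = 0.001,
    background_peak_rate: float = 2.0,
) -> PhantomSpec:
    """4-region reproductive-tract phantom on a 40 x 60 pixel frame.

    Healthy ovary on the left, uterine body across the middle, and a tumor
    with an adjacent blood-filled cyst on the right.
    """
    p = pixel_pitch_um
    return PhantomSpec(
        width_um=60 * p,
        height_um=40 * p,
        pixel_pitch_um=p,
        regions=(
            RegionDef("ovary", ("ellipse", 11 * p, 20 * p, 7 * p, 7 * p), "ovary"),
            RegionDef("uterus", ("rect", 19 * p, 14 * p, 38 * p, 26 * p), "uterus"),
            RegionDef("tumor", ("ellipse", 44 * p, 17 * p, 6 * p, 6.5 * p), "tumor"),
            RegionDef("cyst", ("ellipse", 53 * p, 26 * p, 5.5 * p, 6 * p), "cyst"),
        ),
        profiles={"ovary": _OVARY, "uterus": _UTERUS, "tumor": _TUMOR, "cyst": _CYST},
        pixel_gain_sigma=pixel_gain_sigma,
        mz_jitter_sigma_at_ref=mz_jitter_sigma_at_ref,
        background_peak_rate=background_peak_rate,
        seed=seed,
    )


#: Serum features mirroring the eight tissue/serum-overlapping ions: six
#: measured lower in early-tumor samples, two (Cer(d34:1), LPI(18:0)) higher.
_SERUM_EFFECTS = (
    ("mz436.2826", -1.0),
    ("mz465.3054", -1.0),
    ("mz480.3091", -1.0),
    ("mz524.2975", -1.0),
    ("mz536.5044", 1.0),
    ("mz583.2567", -1.0),
    ("mz599.3209", 1.0),
    ("mz737.5318", -1.0),
)


def default_serum_spec(
    seed: int = 0,
    n_case: int = 14,
    n_control: int = 11,
    effect_scale: float = 1.0,
    sigma: float = 0.2,
) -> SerumSpec:
    """14 early-tumor vs 11 control samples over the 8 overlapping features."""
    features = tuple(
        SerumFeature(fid, effect_scale * sign, 1000.0, sigma)
        for fid, sign in _SERUM_EFFECTS
    )
    return SerumSpec(n_case=n_case, n_control=n_control, features=features, seed=seed)
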