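"""Camera/boom geometry and the pixel-to-ground calibration.

A boom sprayer carries ``n_cameras`` downward-facing cameras that split the
operating width evenly.  The ground size of one pixel follows directly from
the span imaged by one camera divided by its horizontal resolution; no lens
model is involved.  The grille row used for valve decisions must be wider
(on the ground) than the distance the vehicle advances per processed frame,
otherwise a weed can slip through between consecutive decisions.
"""

from __future__ import annotations

from dataclasses import dataclass


class InvalidConfigurationError(ValueError):
    """A geometry/configuration value violates its invariant."""


@dataclass(frozen=True)
class CameraSetup:
    """Boom and camera geometry.

    Parameters
    ----------
    image_width_px, image_height_px : int
        Sensor resolution in pixels.
    boom_width_m : float
        Full operating width of the spray boom [m].
    n_cameras : int
        Cameras mounted on the boom; each images ``boom_width_m / n_cameras``.
    mount_height_m : float
        Camera height above ground [m].  Metadata only; the ground scale is
        fixed by the boom span, not by optics.
    """

    image_width_px: int = 1920
    image_height_px: int = 1080
    boom_width_m: float = 3.3
    n_cameras: int = 2
    mount_height_m: float = 1.0

    def __post_init__(self) -> None:
        for name in ("image_width_px", "image_height_px", "boom_width_m",
                     "n_cameras", "mount_height_m"):
            if getattr(self, name) <= 0:
                raise InvalidConfigurationError(
                    f"CameraSetup.{name} must be positive, got {getattr(self, name)!r}")

    @property
    def camera_span_m(self) -> float:
        """Ground span imaged by a single camera [m]."""
        return self.boom_width_m / self.n_cameras


@dataclass(frozen=True)
class GroundScale:
    """Ground size of one image pixel [mm/px], carried unrounded."""

    mm_per_px: float

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise InvalidConfigurationError(
                f"mm_per_px must be positive, got {self.mm_per_px!r}")

    @property
    def mm_per_px_rounded(self) -> float:
        """Scale rounded to 3 decimals, as quoted in system reports."""
        return round(self.mm_per_px, 3)

    def px_to_mm(self, px: float, *, rounded: bool = False) -> float:
        return px * (self.mm_per_px_rounded if rounded else self.mm_per_px)

    def mm_to_px(self, mm: float) -> float:
        return mm / self.mm_per_px


@dataclass(frozen=True)
class MotionProfile:
    """Vehicle forward speed and the vision pipeline frame rate."""

    speed_kmh: float
    fps: float

    def __post_init__(self) -> None:
        if self.speed_kmh < 0:
            raise InvalidConfigurationError(
                f"speed_kmh must be >= 0, got {self.speed_kmh!r}")
        if self.fps <= 0:
            raise InvalidConfigurationError(f"fps must be > 0, got {self.fps!r}")

    @property
    def speed_mm_s(self) -> float:
        return self.speed_kmh * 1e6 / 3600.0


def ground_scale(setup: CameraSetup) -> GroundScale:
    """Ground size of one pixel for one camera of the boom.

    mm_per_px = (boom_width_m / n_cameras) * 1000 / image_width_px.
    With the reference configuration (3.3 m boom, two cameras, 1920 px) this
    is 0.859 mm/px after 3-decimal rounding.
    """
    return GroundScale(setup.camera_span_m * 1000.0 / setup.image_width_px)


def advance_per_frame(motion: MotionProfile) -> float:
    """Ground distance [mm] the vehicle covers while one frame is processed."""
    return motion.speed_mm_s / motion.fps


@dataclass(frozen=True)
class ConstraintReport:
    """Result of the real-time grille-width check."""

    passed: bool
    margin_mm: float
    grille_width_mm: float
    advance_mm: float


def check_grille_constraint(grille_width_px: int, scale: GroundScale,
                            motion: MotionProfile, *,
                            use_rounded_scale: bool = False) -> ConstraintReport:
    """Check that the grille row is wider on the ground than one frame's advance.

    Passes iff ``grille_width_px * mm_per_px > advance_per_frame(motion)``
    (strict).  ``margin_mm`` is the difference and is negative on failure.
    ``use_rounded_scale`` reproduces reports quoted with the 3-decimal scale
    (60 px * 0.859 = 51.54 mm).
    """
    if grille_width_px <= 0:
        raise InvalidConfigurationError(
            f"grille_width_px must be positive, got {grille_width_px!r}")
    width_mm = scale.px_to_mm(grille_width_px, rounded=use_rounded_scale)
    adv = advance_per_frame(motion)
    return ConstraintReport(passed=width_mm > adv, margin_mm=width_mm - adv,
                            grille_width_mm=width_mm, advance_mm=adv)
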