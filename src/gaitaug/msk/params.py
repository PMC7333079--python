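"""Planar musculoskeletal model parameters and anthropometric scaling.

The model has seven rigid segments (trunk/HAT, two thighs, two shanks, two
feet) connected by six sagittal hinge joints (hips, knees, ankles), giving
nine kinematic degrees of freedom: trunk translation (x, y), trunk
orientation, and the six joint angles.  Sixteen Hill-type muscles (eight per
leg) actuate the joints through constant moment arms; ground contact uses two
compliant points per foot (heel, toe).

Coordinate conventions (documented once, used everywhere):

* global X anterior, Y up; all rotations counterclockwise-positive
* q = [x_hip, y_hip, trunk_angle, hip_R, knee_R, ankle_R, hip_L, knee_L, ankle_L]
* hip flexion positive; knee fully extended at 0 with flexion negative;
  ankle dorsiflexion positive
* segment absolute angles add along the chain
  (phi_thigh = trunk + hip, phi_shank = phi_thigh + knee, ...)

Segment masses, lengths, centre-of-mass offsets, and radii of gyration are
scaled from body weight (BW) and body height (BH) with a standard
anthropometric fraction table (Winter-style); muscle forces scale with BW and
muscle/contact lengths with BH.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

GRAVITY = 9.81

# ---------------------------------------------------------------------------
# Anthropometric fraction table (fractions of total body mass / body height).
# Mass fractions sum to exactly 1; lengths along the segment axis; COM offset
# is the distance of the segment COM from the proximal joint as a fraction of
# the segment length; rgyr is the radius of gyration about the COM as a
# fraction of segment length.
# ---------------------------------------------------------------------------
WINTER_TABLE = {
    #            mass_frac  len_frac   com_frac  rgyr_frac
    "trunk": dict(mass=0.678, length=0.288, com=0.626, rgyr=0.496),
    "thigh": dict(mass=0.100, length=0.245, com=0.433, rgyr=0.323),
    "shank": dict(mass=0.0465, length=0.246, com=0.433, rgyr=0.302),
    "foot": dict(mass=0.0145, length=0.152, com=0.500, rgyr=0.475),
}

SEGMENT_NAMES = ("trunk", "thigh_r", "shank_r", "foot_r", "thigh_l", "shank_l", "foot_l")
JOINT_NAMES = ("hip_r", "knee_r", "ankle_r", "hip_l", "knee_l", "ankle_l")

MUSCLE_NAMES_ONE_LEG = (
    "iliopsoas",
    "glutei",
    "hamstrings",
    "rectus_femoris",
    "vasti",
    "gastrocnemius",
    "soleus",
    "tibialis_anterior",
)

# Per-muscle reference values for a 75 kg / 1.75 m adult.  Forces scale with
# BW, lengths with BH.  Moment arms are constant per muscle-joint pair
# (hip, knee, ankle), signed so that the generalized torque on coordinate q_j
# is +F * r_j with the joint sign conventions above (flexors of the hip and
# dorsiflexors of the ankle have positive arms, knee extensors positive).
_MUSCLE_REF = {
    # name:              fmax (N), lopt (m), lslack (m),  arms (hip, knee, ankle) (m)
    "iliopsoas": dict(fmax=1500.0, lopt=0.102, lslack=0.142, arms=(0.050, 0.0, 0.0)),
    "glutei": dict(fmax=3000.0, lopt=0.200, lslack=0.157, arms=(-0.062, 0.0, 0.0)),
    "hamstrings": dict(fmax=3000.0, lopt=0.104, lslack=0.334, arms=(-0.072, -0.034, 0.0)),
    "rectus_femoris": dict(fmax=1200.0, lopt=0.081, lslack=0.398, arms=(0.034, 0.050, 0.0)),
    "vasti": dict(fmax=7000.0, lopt=0.093, lslack=0.223, arms=(0.0, 0.042, 0.0)),
    "gastrocnemius": dict(fmax=3000.0, lopt=0.055, lslack=0.420, arms=(0.0, -0.020, -0.053)),
    "soleus": dict(fmax=4000.0, lopt=0.055, lslack=0.245, arms=(0.0, 0.0, -0.053)),
    "tibialis_anterior": dict(fmax=1500.0, lopt=0.082, lslack=0.317, arms=(0.0, 0.0, 0.037)),
}

_ACT_TAU = 0.010  # activation time constant (s)
_DEACT_TAU = 0.040  # deactivation time constant (s)


class ValidationError(ValueError):
    """Raised when model inputs violate their physical preconditions."""


@dataclass(frozen=True)
class Anthropometry:
    """Subject body weight (kg) and body height (m)."""

    body_weight: float
    body_height: float

    def __post_init__(self):
        if not (self.body_weight > 0 and np.isfinite(self.body_weight)):
            raise ValidationError(f"body_weight must be positive, got {self.body_weight}")
        if not (self.body_height > 0 and np.isfinite(self.body_height)):
            raise ValidationError(f"body_height must be positive, got {self.body_height}")


@dataclass
class Segment:
    name: str
    mass: float
    length: float
    com_offset: float  # distance of COM from proximal joint along the axis (m)
    inertia: float  # moment of inertia about the COM (kg m^2)


@dataclass
class Muscle:
    name: str
    side: str  # 'r' | 'l'
    fmax: float  # maximum isometric force (N)
    lopt: float  # optimal contractile-element length (m)
    lslack: float  # tendon slack length (m)
    arms: tuple  # constant moment arms (hip, knee, ankle) of its own side (m)
    tau_act: float = _ACT_TAU
    tau_deact: float = _DEACT_TAU


@dataclass
class ContactParams:
    """Smoothed compliant heel/toe contact shared by both feet.

    Vertical force is a linear spring on a first-order deformation state with
    velocity-dependent (bounded, sign-safe) damping; horizontal force is a
    friction-cone-saturated shear spring on a second deformation state.
    """

    k_normal: float  # vertical stiffness (N/m)
    k_shear: float  # horizontal stiffness (N/m)
    mu: float = 1.0  # friction coefficient
    tau_contact: float = 0.01  # deformation tracking time constant (s)
    tau_release: float = 0.05  # shear release time constant out of contact (s)
    damping_ratio: float = 0.75  # bounded velocity damping factor (<1 keeps Fy >= 0)
    v_damp: float = 0.2  # damping velocity scale (m/s)
    pen_smooth: float = 1.0e-3  # smooth positive-part length scale (m)
    force_eps: float = 10.0  # regularizer in the friction saturation (N)


@dataclass
class ModelParams:
    """Scaled planar 7-segment, 16-muscle, 4-contact-point parameter set."""

    anthro: Anthropometry
    segments: dict  # name -> Segment
    muscles: list  # 16 Muscle, right leg first
    contact: ContactParams
    # foot geometry relative to the ankle, in the foot frame (m)
    heel_offset: tuple = (0.0, 0.0)
    toe_offset: tuple = (0.0, 0.0)
    foot_com_offset: tuple = (0.0, 0.0)
    ankle_height: float = 0.0
    gravity: float = GRAVITY
    # ideal-torque actuation scale for the torque-driven mode (N m per unit control)
    torque_scale: float = 0.0
    # passive joint properties
    passive_stiffness: float = 200.0  # N m / rad^2 beyond the free range
    passive_damping: float = 0.3  # N m s / rad
    joint_free_range: tuple = field(
        default_factory=lambda: (
            (-0.7, 2.1),  # hip (rad)
            (-2.4, 0.05),  # knee
            (-0.9, 0.7),  # ankle
        )
    )
    schema_version: str = "1"

    @property
    def body_weight(self) -> float:
        return self.anthro.body_weight

    @property
    def body_height(self) -> float:
        return self.anthro.body_height

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def leg_length(self) -> float:
        return (
            self.segments["thigh_r"].length
            + self.segments["shank_r"].length
            + self.ankle_height
        )


def scale_model(anthro: Anthropometry) -> ModelParams:
    """Scale the planar model to a subject's body weight and height.

    Segment masses, lengths, COM offsets, and inertias come from the embedded
    anthropometric fraction table; muscle maximum forces scale with BW and
    muscle lengths / contact geometry with BH.

    Raises
    ------
    ValidationError
        If body weight or height is not positive.
    """
    bw, bh = anthro.body_weight, anthro.body_height

    segments = {}
    for base, frac in WINTER_TABLE.items():
        length = frac["length"] * bh
        mass = frac["mass"] * bw
        inertia = mass * (frac["rgyr"] * length) ** 2
        names = ("trunk",) if base == "trunk" else (f"{base}_r", f"{base}_l")
        m_each = mass if base == "trunk" else mass / 1.0
        for nm in names:
            segments[nm] = Segment(
                name=nm,
                mass=m_each,
                length=length,
                com_offset=frac["com"] * length,
                inertia=inertia,
            )

    f_scale = bw / 75.0
    l_scale = bh / 1.75
    muscles = []
    for side in ("r", "l"):
        for name in MUSCLE_NAMES_ONE_LEG:
            ref = _MUSCLE_REF[name]
            muscles.append(
                Muscle(
                    name=name,
                    side=side,
                    fmax=ref["fmax"] * f_scale,
                    lopt=ref["lopt"] * l_scale,
                    lslack=ref["lslack"] * l_scale,
                    arms=tuple(a * l_scale for a in ref["arms"]),
                )
            )

    contact = ContactParams(
        k_normal=1.0e5 * f_scale,
        k_shear=5.0e4 * f_scale,
    )

    ankle_height = 0.039 * bh
    foot_len = WINTER_TABLE["foot"]["length"] * bh
    heel = (-0.20 * foot_len, -ankle_height)
    toe = (0.80 * foot_len, -ankle_height)
    foot_com = (0.30 * foot_len, -0.5 * ankle_height)

    return ModelParams(
        anthro=anthro,
        segments=segments,
        muscles=muscles,
        contact=contact,
        heel_offset=heel,
        toe_offset=toe,
        foot_com_offset=foot_com,
        ankle_height=ankle_height,
        torque_scale=0.05 * bw * GRAVITY * bh,
    )


def model_to_dict(p: ModelParams) -> dict:
    """Serializable representation (JSON/YAML-friendly)."""
    d = asdict(p)
    return d
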