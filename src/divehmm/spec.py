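"""Model skeletons for the semi-supervised dive HMM.

A model is defined over an ordered set of behavioural states.  The first two
states are the *known* non-diving states (haulout and surface): a record's
type pins it to the matching state, and those states emit only the behaviour
duration.  The remaining states are dive states, characterised by all five
data streams (duration, hunting depth, proportion of dive spent hunting,
bathymetry-contact indicator, salinity at hunting depth).

Transition probabilities follow a multinomial logit with the diagonal as the
reference category, driven by a design row built from local time of day
(as a circular cosine/sine pair), week of year, and optionally their
interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: record types in the behavioural sequence
RECORD_TYPES = ("haulout", "surface", "dive")

#: design options for the transition covariates
DESIGNS = ("full", "no_interaction", "intercept")

#: rules for the initial state distribution of each individual
INITIAL_RULES = ("stationary", "uniform", "estimated")

DEFAULT_DIVE_NAMES = ("shallow", "epipelagic", "pelagic", "benthic")


@dataclass(frozen=True)
class HmmSpec:
    """Structure of a dive HMM: states, known-state mask and covariate design.

    Parameters
    ----------
    state_names
        Ordered state labels.  The first two must be the known non-diving
        states (haulout, surface); every further name is a dive state.
    covariate_design
        ``"full"`` uses (1, cos h, sin h, w, cos h * w, sin h * w) where h is
        local hour and w the centred/scaled week of year; ``"no_interaction"``
        drops the two product columns; ``"intercept"`` yields a homogeneous
        chain.
    initial
        Rule for the initial state distribution per individual:
        the stationary distribution of the transition matrix at the first
        record's covariates, a uniform distribution, or freely estimated
        logits.
    week_center, week_scale
        Centring/scaling applied to the week covariate inside the design row
        for optimiser conditioning.  Reported coefficients are on this scale.
    """

    state_names: tuple[str, ...] = ("haulout", "surface") + DEFAULT_DIVE_NAMES
    covariate_design: str = "full"
    initial: str = "stationary"
    week_center: float = 15.0
    week_scale: float = 10.0

    def __post_init__(self) -> None:
        if len(self.state_names) < 3:
            raise ValueError("need the two known states plus >= 1 dive state")
        if len(set(self.state_names)) != len(self.state_names):
            raise ValueError("state names must be unique")
        if self.covariate_design not in DESIGNS:
            raise ValueError(f"unknown covariate design {self.covariate_design!r}")
        if self.initial not in INITIAL_RULES:
            raise ValueError(f"unknown initial rule {self.initial!r}")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def known_states(self) -> dict[str, int]:
        """Map record type -> pinned state index for the non-dive states."""
        return {"haulout": 0, "surface": 1}

    @property
    def dive_state_indices(self) -> np.ndarray:
        return np.arange(2, self.n_states)

    @property
    def n_dive_states(self) -> int:
        return self.n_states - 2

    @property
    def dive_state_names(self) -> tuple[str, ...]:
        return self.state_names[2:]

    @property
    def n_design(self) -> int:
        return {"full": 6, "no_interaction": 4, "intercept": 1}[self.covariate_design]

    def design_row(self, hour, week) -> np.ndarray:
        """Design row(s) for the transition logits at given covariates.

        Accepts scalars or equal-length arrays; returns shape (K,) or (n, K).
        """
        hour = np.asarray(hour, dtype=float)
        week = np.asarray(week, dtype=float)
        scalar = hour.ndim == 0 and week.ndim == 0
        hour, week = np.broadcast_arrays(np.atleast_1d(hour), np.atleast_1d(week))
        angle = 2.0 * np.pi * hour / 24.0
        c, s = np.cos(angle), np.sin(angle)
        w = (week - self.week_center) / self.week_scale
        one = np.ones_like(c)
        if self.covariate_design == "full":
            X = np.column_stack([one, c, s, w, c * w, s * w])
        elif self.covariate_design == "no_interaction":
            X = np.column_stack([one, c, s, w])
        else:
            X = one[:, None]
        return X[0] if scalar else X

    def allowed_state_mask(self) -> np.ndarray:
        """(3, N) boolean: which states each record type may occupy.

        Row order follows :data:`RECORD_TYPES`.  Haulout and surface records
        are pinned to their known state; dive records may occupy any dive
        state but never a non-diving one.
        """
        N = self.n_states
        mask = np.zeros((3, N), dtype=bool)
        mask[0, 0] = True
        mask[1, 1] = True
        mask[2, 2:] = True
        return mask

    def state_of_record_type(self, record_type: str) -> int | None:
        return self.known_states.get(record_type)


def spec_for_sex(sex: str, **kwargs) -> HmmSpec:
    """Convenience spec constructors mirroring the two fitted models.

    Females are described by a six-state model (four dive states including a
    pelagic one); males by a five-state model (three dive states, no pelagic).
    """
    sex = sex.upper()[:1]
    if sex == "F":
        names = ("haulout", "surface", "shallow", "epipelagic", "pelagic", "benthic")
    elif sex == "M":
        names = ("haulout", "surface", "shallow", "epipelagic", "benthic")
    else:
        raise ValueError("sex must be 'F' or 'M'")
    return HmmSpec(state_names=names, **kwargs)
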