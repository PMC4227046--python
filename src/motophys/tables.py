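"""Published per-group property distributions for neonatal mouse spinal motoneurons.

Each entry is the summary line of one population table cell: mean, SD, range
and number of observations, for one (genotype, firing pattern) group. The
electrophysiology block covers passive properties, rheobase, spike threshold,
single-spike shape and discharge measures; the morphology block covers the
dendritic-tree metrics obtained from partial slice reconstructions.

These entries parameterize the synthetic-population generator
(:mod:`motophys.synthgen`): every property is drawn from a truncated normal
whose realized mean/SD are moment-matched to the printed values (see
:mod:`motophys.sampling`).

Genotypes: ``WT`` (wild-type littermate) and ``mSOD1`` (SOD1-G93A ALS model).
Patterns: ``immediate`` (S-type signature: discharge from pulse onset) and
``delayed`` (F-type signature: discharge seconds after onset at rheobase).
"""

from __future__ import annotations

from dataclasses import dataclass

GENOTYPES = ("WT", "mSOD1")
PATTERNS = ("immediate", "delayed")


@dataclass(frozen=True)
class Row:
    """One summary-table cell: mean +/- SD with range and N."""

    mean: float
    sd: float
    min: float
    max: float
    n: int

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"mean {self.mean} outside range [{self.min}, {self.max}]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


# --- electrophysiological properties, per (genotype, pattern) -----------------

ELECTRO: dict[tuple[str, str], dict[str, Row]] = {
    ("WT", "delayed"): {
        "V_rest": Row(-64, 3, -70, -56, 63),         # mV
        "G_in": Row(52, 28, 10, 151, 63),            # nS
        "rheobase": Row(1.2, 0.6, 0.3, 2.8, 57),     # nA
        "V_threshold": Row(-33, 7, -47, -17, 58),    # mV
        "delta_V": Row(31, 8, 17, 49, 59),           # mV
        "recruitment": Row(1.1, 0.6, 0.1, 2.8, 51),  # nA
        "ap_amplitude": Row(89, 13, 66, 121, 29),    # mV
        "ap_halfwidth": Row(1.4, 0.5, 0.7, 2.5, 29), # ms
        "ahp_tau": Row(27, 9, 11, 50, 21),           # ms
        "f_half_second": Row(30, 7, 17, 49, 42),     # Hz
    },
    ("mSOD1", "delayed"): {
        "V_rest": Row(-65, 3, -70, -59, 31),
        "G_in": Row(54, 30, 22, 153, 31),
        "rheobase": Row(1.1, 0.5, 0.3, 2.6, 30),
        "V_threshold": Row(-31, 10, -50, -10, 30),
        "delta_V": Row(33, 10, 13, 50, 31),
        "recruitment": Row(1.1, 0.5, 0.3, 2.5, 29),
        "ap_amplitude": Row(87, 11, 71, 111, 19),
        "ap_halfwidth": Row(1.3, 0.4, 0.6, 2.2, 19),
        "ahp_tau": Row(23, 5, 15, 34, 12),
        "f_half_second": Row(29, 6, 13, 42, 26),
    },
    ("WT", "immediate"): {
        "V_rest": Row(-65, 3, -71, -59, 31),
        "G_in": Row(33, 24, 6, 98, 31),
        "rheobase": Row(0.6, 0.4, 0.05, 1.6, 29),
        "V_threshold": Row(-44, 7, -50, -41, 30),
        "delta_V": Row(20, 7, 8, 31, 30),
        "recruitment": Row(0.6, 0.5, 0.07, 2.0, 25),
        "ap_amplitude": Row(84, 11, 66, 104, 21),
        "ap_halfwidth": Row(1.7, 0.4, 1.1, 2.9, 21),
        "ahp_tau": Row(42, 12, 21, 60, 11),
        "gain": Row(35, 22, 11, 80, 12),             # Hz/nA, primary range
    },
    ("mSOD1", "immediate"): {
        "V_rest": Row(-64, 2, -70, -60, 18),
        "G_in": Row(33, 16, 6, 62, 18),
        "rheobase": Row(0.3, 0.2, 0.1, 0.6, 16),
        "V_threshold": Row(-49, 6, -50, -30, 17),
        "delta_V": Row(14, 5, 6, 21, 17),
        "recruitment": Row(0.3, 0.3, 0.07, 1.0, 15),
        "ap_amplitude": Row(81, 15, 61, 110, 13),
        "ap_halfwidth": Row(1.8, 0.6, 0.9, 3.1, 13),
        "ahp_tau": Row(48, 27, 19, 91, 7),
        "gain": Row(26, 8, 16, 41, 9),
    },
}

# Proportion of cells showing mixed-mode oscillations between spikes at low
# drive, per group (counts from the ramp/MMO survey).
MMO_PREVALENCE: dict[tuple[str, str], tuple[int, int]] = {
    ("WT", "delayed"): (49, 50),
    ("mSOD1", "delayed"): (31, 31),
    ("WT", "immediate"): (13, 15),
    ("mSOD1", "immediate"): (3, 11),
}

# Group sizes of the firing-pattern survey (delayed count, immediate count).
PATTERN_COUNTS: dict[str, tuple[int, int]] = {"WT": (63, 31), "mSOD1": (31, 18)}

# --- morphological properties -------------------------------------------------

MORPHO: dict[tuple[str, str], dict[str, Row]] = {
    ("WT", "delayed"): {
        "soma_area": Row(630, 160, 350, 1000, 60),        # um^2 (external scalar)
        "n_primary": Row(6.4, 2.0, 4, 12, 14),
        "n_branch_points": Row(44, 14, 26, 72, 14),
        "total_length": Row(8.3, 2.9, 2.3, 14, 14),       # mm
        "dendritic_path": Row(296, 135, 5, 687, 653),     # um, per-terminal pool
        "terminal_segment": Row(112, 93, 4, 457, 618),    # um, per-terminal pool
    },
    ("mSOD1", "delayed"): {
        "soma_area": Row(620, 140, 270, 890, 31),
        "n_primary": Row(6.7, 1.2, 5, 9, 14),
        # Branching-point summary is not printed for this group; reconstructed
        # from the length-vs-branching regression (8.7 mm at 0.18 mm/branch).
        "n_branch_points": Row(48, 16, 24, 90, 14),
        "total_length": Row(8.7, 3.8, 3.8, 16.5, 14),
        "dendritic_path": Row(293, 139, 15, 840, 449),
        "terminal_segment": Row(108, 102, 3, 742, 447),
    },
    ("WT", "immediate"): {
        "soma_area": Row(530, 180, 260, 940, 30),
        "n_primary": Row(6.3, 2.7, 3, 10, 10),
        "n_branch_points": Row(27, 13, 13, 52, 10),
        "total_length": Row(5.3, 1.5, 3.0, 8.0, 10),
        "dendritic_path": Row(252, 141, 11, 803, 281),
        "terminal_segment": Row(108, 91, 5, 545, 296),
    },
    ("mSOD1", "immediate"): {
        "soma_area": Row(454, 110, 250, 640, 17),
        "n_primary": Row(6.4, 4.0, 2, 13, 5),
        "n_branch_points": Row(27, 14, 9, 45, 5),
        "total_length": Row(3.6, 0.3, 3.3, 4.1, 5),
        "dendritic_path": Row(181, 157, 11, 685, 180),
        "terminal_segment": Row(81, 92, 4, 584, 178),
    },
}


def electro_rows(genotype: str, pattern: str) -> dict[str, Row]:
    _check_group(genotype, pattern)
    return ELECTRO[(genotype, pattern)]


def morpho_rows(genotype: str, pattern: str) -> dict[str, Row]:
    _check_group(genotype, pattern)
    return MORPHO[(genotype, pattern)]


def _check_group(genotype: str, pattern: str) -> None:
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {PATTERNS}")
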