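"""Configuration dataclasses and seed plumbing shared by all stages."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

#: Symmetric extension applied to binding peaks before PETs are anchored.
DEFAULT_EXTENSION_BP = 1500

#: Span cutoff below which a convergent same-chromosome PET is treated as a
#: self-circularization artifact (order of sheared-fragment size x safety
#: factor; the fragments average ~500 bp).
DEFAULT_SELF_CIRC_MAX_SPAN = 3000


def substream(seed: int, label: str) -> np.random.Generator:
    """Derive an independent, reproducible generator for a named stage.

    All randomness in the package flows from one integer seed; each stage
    draws from its own substream so stage order never perturbs another
    stage's random numbers.
    """
    key = zlib.crc32(label.encode("utf-8"))  # stable across processes
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF, spawn_key=(key,))
    return np.random.default_rng(ss)


@dataclass
class SimConfig:
    """Parameters of the synthetic ChIA-PET experiment.

    The defaults are the desk-scale study conditions used throughout the
    package: a 10 Mb single-chromosome genome, 300 binding peaks, 150
    planted loops with a Poisson PET rate of 10, and 100,000 background
    PETs whose genomic distance follows a truncated power law
    p(d) ~ d**(-decay_alpha) — the heavy-tailed contact-frequency decay of
    random ligation between loci on the same DNA molecule.
    """

    genome: Sequence[tuple[str, int]] = (("chr1", 10_000_000),)
    n_peaks: int = 300
    peak_width_bp: int = 2000
    n_true_loops: int = 150
    loop_pet_rate: float = 10.0
    n_background_pets: int = 100_000
    decay_alpha: float = 1.2
    min_distance_bp: int = 10_000
    max_distance_bp: int = 5_000_000
    duplicate_rate: float = 0.05
    self_circ_rate: float = 0.05
    read_len_bp: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.n_peaks < 0 or self.n_true_loops < 0 or self.n_background_pets < 0:
            raise ValueError("counts must be >= 0")
        for name in ("duplicate_rate", "self_circ_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.decay_alpha <= 0:
            raise ValueError("decay_alpha must be > 0")
        if self.min_distance_bp >= self.max_distance_bp:
            raise ValueError("min_distance_bp must be < max_distance_bp")
        if not self.genome:
            raise ValueError("genome must list at least one chromosome")
        for chrom, length in self.genome:
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    def rng(self, label: str) -> np.random.Generator:
        return substream(self.seed, label)


@dataclass
class CallerConfig:
    """Parameters of the DMR interaction caller.

    fdr
        Target empirical FDR: at the chosen Z threshold, no more than this
        fraction of passing interactions may come from the rewired control.
    n_bins_per_octave
        "Local" Z statistics are computed in log2-spaced distance bins
        (interaction frequency decays roughly log-linearly with distance);
        this sets how many bins each doubling of distance is split into.
    n_rewires
        Independent rewired data sets; counts above threshold are scaled by
        1/n_rewires.  One control set is the default.
    sd_floor
        Minimum standard deviation used in the Z denominator, protecting
        sparse bins from division blow-ups.
    min_pairs_per_bin
        A bin whose same-chromosome pair universe is smaller than this is
        pooled with its neighbours (widening one bin each side) before the
        bin mean/SD are computed.
    include_structural_zeros
        Whether the rewired-pair universe for the bin mean/SD includes
        same-chromosome anchor pairs with zero rewired PETs.  Excluding
        them inflates the mean and destroys FDR control; the switch exists
        for sensitivity analysis only.
    """

    fdr: float = 0.10
    n_bins_per_octave: int = 1
    n_rewires: int = 1
    sd_floor: float = 0.5
    min_pairs_per_bin: int = 20
    max_rewire_tries: int = 50
    include_structural_zeros: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must be in (0, 1)")
        if self.n_rewires < 1:
            raise ValueError("n_rewires must be >= 1")
        if self.n_bins_per_octave < 1:
            raise ValueError("n_bins_per_octave must be >= 1")
        if self.sd_floor < 0:
            raise ValueError("sd_floor must be >= 0")

    def rng(self, label: str) -> np.random.Generator:
        return substream(self.seed, label)

    def to_dict(self) -> dict:
        return asdict(self)
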