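"""Structural constants of the Go/No-go RT-CIT paradigm.

The multiple-probes protocol intermixes every item within each block:
2 probes (the examinee's own first and last name), 8 matched irrelevant
names, 2 target cities requiring a "familiar" response, and 2 no-go
animals requiring response withholding.  Each item appears six times per
block over four blocks, giving 84 trials per block and 336 in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: canonical stimulus-type vocabulary used in all trial tables
STIM_TYPES = ("probe", "irrelevant", "target", "nogo")

#: go responses; no-go trials require ``none``
RESPONSES = ("familiar", "unfamiliar", "none")


@dataclass(frozen=True)
class DesignSpec:
    """Trial-schedule and timing constants of the paradigm.

    All durations are in milliseconds.  The defaults encode the study
    design: 14 items x 6 repetitions x 4 blocks, 1500 ms stimulus
    duration, an 800 ms response deadline ("TOO SLOW" feedback), and a
    fixation ISI drawn from {250, 500, 750} ms.
    """

    n_probes: int = 2
    n_irrelevants: int = 8
    n_targets: int = 2
    n_nogo: int = 2
    reps_per_block: int = 6
    n_blocks: int = 4
    isi_options_ms: tuple[int, ...] = (250, 500, 750)
    stim_duration_ms: float = 1500.0
    deadline_ms: float = 800.0
    min_valid_rt_ms: float = 150.0

    def __post_init__(self) -> None:
        counts = (self.n_probes, self.n_irrelevants, self.n_targets,
                  self.n_nogo, self.reps_per_block, self.n_blocks)
        if any(c < 0 for c in counts):
            raise ValueError("item counts, repetitions and blocks must be >= 0")
        if self.n_items == 0 or self.reps_per_block == 0 or self.n_blocks == 0:
            raise ValueError("design must contain at least one trial")
        if not self.isi_options_ms:
            raise ValueError("isi_options_ms must be non-empty")
        for dur in (*self.isi_options_ms, self.stim_duration_ms,
                    self.deadline_ms, self.min_valid_rt_ms):
            if dur <= 0:
                raise ValueError("all durations must be strictly positive")
        if self.min_valid_rt_ms >= self.deadline_ms:
            raise ValueError("min_valid_rt_ms must be below deadline_ms")

    @property
    def n_items(self) -> int:
        return self.n_probes + self.n_irrelevants + self.n_targets + self.n_nogo

    @property
    def trials_per_block(self) -> int:
        return self.n_items * self.reps_per_block

    @property
    def total_trials(self) -> int:
        return self.trials_per_block * self.n_blocks

    @property
    def n_nogo_trials(self) -> int:
        """Total no-go trials in a full session (48 under the defaults)."""
        return self.n_nogo * self.reps_per_block * self.n_blocks

    def item_labels(self) -> list[tuple[str, str]]:
        """(item_id, stim_type) pairs, e.g. ``("probe_1", "probe")``."""
        out: list[tuple[str, str]] = []
        for stim, count in (("probe", self.n_probes),
                            ("irrelevant", self.n_irrelevants),
                            ("target", self.n_targets),
                            ("nogo", self.n_nogo)):
            out.extend((f"{stim}_{i + 1}", stim) for i in range(count))
        return out
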