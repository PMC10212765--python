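"""Shared configuration for the numbered analysis drivers.

The cohort emulates a matched primary/recurrent study: 4 tissue pairs,
~1 mm^2 fields scaled down to 512 x 512 px at 1 um/px with 300 cells
each, a +0.10 cytotoxic-T abundance shift and a +1 log2 PD-1 intensity
shift on Tregs in the recurrent samples, and monocyte-CD8 attraction in
recurrent tissue only.
"""

from pathlib import Path

from imcspatial import synth

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

N_PAIRS = 4
SEED = 17
ABUNDANCE_SHIFT = {"cytotoxic T cell": 0.10}
MFI_SHIFT = {("Treg", "PD-1"): 1.0}
RECURRENT_ATTRACTION = [("monocyte", "cytotoxic T cell", 0.9)]
RADIUS_UM = 15.0
N_PERM = 1000


def base_simulation() -> synth.SimulationConfig:
    return synth.SimulationConfig(field_size_px=(512, 512), n_cells=300)


def sample_ids():
    return [f"pair{i + 1}_{cond}" for i in range(N_PAIRS)
            for cond in ("primary", "recurrent")]


def pair_map():
    return {f"pair{i + 1}": (f"pair{i + 1}_primary", f"pair{i + 1}_recurrent")
            for i in range(N_PAIRS)}
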