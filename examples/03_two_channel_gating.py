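"""Two-channel overlap gating (reflectance + fluorescence style).

The primary channel holds three bright curvilinear axons on a dark noisy
background; the second "gate" channel is bright over only two of them.
The pipeline segments both channels and keeps only the primary components
that overlap the gate mask, mirroring how a label-free signal can be
restricted to a genetically labeled subset.
"""

from ndnt import run_pipeline_arrays
from ndnt.synthetic import generate_phantom, preset_pipeline_settings, scenario_presets

phantom = generate_phantom(scenario_presets()["score_like"], seed=5)
settings = preset_pipeline_settings("score_like")

config = {
    "ndnt": settings["ndnt"],
    "identify": {
        **settings["identify"],
        "overlap_gate": {**settings["gate"], "ndnt": settings["gate_ndnt"]},
    },
}
result = run_pipeline_arrays(phantom.volume, config, gate_volume=phantom.gate_volume)

print(f"planted axons: {sum(1 for c in phantom.truth_classes.values() if c == 'axon')}")
print(f"axons present in the gate channel: {len(phantom.gated_ids)}")
print(f"components surviving the overlap gate: {result.n_components}")

# Expected: 3 planted axons, 2 in the gate channel, and exactly 2
# surviving components — the gate drops the unlabeled axon.
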