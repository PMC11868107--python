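"""Simulate an assessment with known ground truth and recover it.

The fixture world engineers a lexicon and embeddings so every error
category is constructible; the simulator then draws categories, builds
responses satisfying their defining inequalities, and the full pipeline
should classify every attempt back into its generating category.
"""

from girasol import (
    CATEGORY_COLUMNS,
    PipelineConfig,
    SimulationSpec,
    make_fixture_world,
    run_pipeline,
    simulate_responses,
)

world = make_fixture_world(n_items=15, seed=42)
spec = SimulationSpec(n_items=120, seed=42)
raw, truth = simulate_responses(spec, list(world.items), world.wordlist, world.embeddings)
print(f"simulated {len(raw)} presentations -> {len(truth)} attempts")

config = PipelineConfig(
    wordlist=world.wordlist, embeddings=world.embeddings, drop_blank=False
)
classified = run_pipeline(raw, config)

predicted = classified[CATEGORY_COLUMNS].idxmax(axis=1)
recovery = (predicted.to_numpy() == truth["category"].to_numpy()).mean()
print(f"category recovery: {recovery:.1%}")
print(truth["category"].value_counts().to_string())
# Recovery is 100%: every simulated attempt satisfies its category's
# defining inequalities by construction, and the classifier applies
# exactly those inequalities.
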