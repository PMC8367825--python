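"""Learn three-zone triage thresholds from a cohort and classify scores.

Thresholds follow the mean-of-means rule: t_opml is the midpoint of the
normal and OPML class means, t_scc the midpoint of the OPML and SCC means.
The model registry keeps an append-only log and immutable versioned
snapshots, so every fitted model can be replayed.
"""

import tempfile

from oralmsi import CohortSpec, ModelRegistry, classify, generate_cohort, update_model

records = generate_cohort(
    CohortSpec(n_per_class={"normal": 60, "OPML": 60, "SCC": 60}, seed=21)
)

with tempfile.TemporaryDirectory() as tmp:
    registry = ModelRegistry(tmp)
    model = update_model(registry, records, group="all_sites")
    print(f"model v{model.version} ({model.group})")
    print(f"  t_opml = {model.t_opml:.3f}   t_scc = {model.t_scc:.3f}")
    for score in (1.4, 2.51, 4.2):
        cls, color = classify(score, model)
        print(f"  score {score:4.2f} -> {cls:8s} ({color})")
print("Scores below t_opml are normal/green, between the thresholds")
print("suspect/yellow, and at or above t_scc critical/red.")
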