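"""Score and rank clone populations by susceptibility to exposure.

Each clone has a planted dose-response profile: its cluster-group 1
(large "healthy" morphology) fraction drops by a at control->low dose
and by b at low->high.  The susceptibility score (a-b)/(a+b) is +1 when
the whole shift happens at low dose (most susceptible) and -1 when it
happens only at high dose (resilient).  Scores are reported relative to
the parental population.
"""

from morphotype import synthetic as syn
from morphotype.susceptibility import (
    SusceptibilityInput,
    normalize_to_parental,
    rank_populations,
    score_table,
    susceptibility_score,
)

results = []
for panel in syn.default_clone_panel():
    series = syn.generate_condition_series(panel, n_cells=2000, seed=4)
    fr = {dose: (t["cg_id"] == 1).mean() for dose, t in series.tables.items()}
    res = susceptibility_score(
        SusceptibilityInput(panel.clone_id, fr["control"], fr["low"], fr["high"])
    )
    print(
        f"{panel.clone_id:10s} CG1: {fr['control']:.3f} -> {fr['low']:.3f} -> "
        f"{fr['high']:.3f}   score {res.score:+.3f} "
        f"(planted {panel.planted_score:+.3f})"
    )
    results.append(res)

normalize_to_parental(results, "parental")
ranked = rank_populations(results)
print("\nranking, most susceptible first (normalized to parental = 0):")
print(score_table(ranked).round(3).to_string(index=False))
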