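"""Derive per-contest rosters and the 15 relative predictors.

For one contest this prints both adult rosters (ages in days, dominance from
mate-guarding within 180 d, weights from the nearest valid weighing within
120 d) and the focal-minus-rival predictor vector the contest models consume.
"""

import grouprhp as g

pop_cfg = g.PopulationConfig(seed=1)
tables = g.generate_population(pop_cfg)
contests, _ = g.generate_contests(
    tables, g.ContestGenConfig(n_contests=50, seed=2), pop_cfg
)
tables.contests = contests

cid = contests["contest_id"].iloc[0]
focal, rival = g.build_roster(tables, cid)
print(f"contest {cid}: {focal['group_id'].iloc[0]} (focal, n={len(focal)}) vs "
      f"{rival['group_id'].iloc[0]} (rival, n={len(rival)})")
print(focal[["individual_id", "sex", "age_days", "dominant", "weight_g"]]
      .head(8).to_string(index=False))

vec = g.relative_predictors(focal, rival)
print("\nrelative predictors (focal minus rival); positive favours the focal group:")
print(vec.round(2).to_string())
print("\nrel_n_males > 0 means the focal group fields more adult males; "
      "rel_max_age_males > 0 means its oldest male is older.")
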