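# dyadarc

Analysis pipeline for dyadic competitive reaction-time sessions: from
per-frame facial action-unit (AU) intensity tables and round-by-round
trial logs to prototypic-emotion scores, high-affect classification,
escalation/retaliation dynamics, actor–partner interdependence (APIM)
and mediation models — plus a seeded generative simulator of whole
couples' sessions so every stage is exercisable with no external data.

## Layout

| module               | role |
|----------------------|------|
| `dyadarc.simulate`   | generative simulator: rigged win/loss, 1–8 blast selections with matching and per-player escalation asymmetry, negativity with actor/partner carry-over, exponential decay across forced/elective breaks, AU emission |
| `dyadarc.scoring`    | AU-intensity CSV reader (`AUxx_r` dialect), prototypic emotion scoring (happiness {6,12}; anger {4,23}; disgust {9}; negative = max(anger, disgust)), event-window means |
| `dyadarc.features`   | affect/trial joins, mean+1SD high-affect flags, win-streak compression, compounding categories, timing features |
| `dyadarc.dynamics`   | escalation coefficients (−7..+7), match/escalate/de-escalate splits, within-couple asymmetry, matching correlations, escalation-over-time slope |
| `dyadarc.models`     | two-intercept role-stratified APIM (couple-level random intercept, ML) and forced-break mediation with couple-clustered bootstrap |
| `dyadarc.stats`      | rank-sum test with continuity + tie corrections and exact enumeration, effect size r, Cronbach's alpha, JZS Bayes factors, 12-item trait-aggression scoring |
| `dyadarc.report` / `dyadarc.cli` | pipeline orchestration, study summaries, `dyadarc` CLI |

## CLI

```sh
# simulate a study (trial log + per-player AU streams)
dyadarc simulate --config cfg.yaml --seed 1 --out simdir

# run the full analysis
dyadarc run --trials simdir/trials.csv --au simdir/au --out outdir --seed 1

# individual stages
dyadarc score    --au simdir/au/c001_p1.csv --out emotions.csv
dyadarc features --trials simdir/trials.csv --emotions emodir --out featdir
dyadarc dynamics --compressed featdir/compressed.csv --trials simdir/trials.csv --out dyndir
dyadarc apim     --table apim_table.csv
dyadarc mediate  --trials mediation.csv --boot 5000 --seed 1
```

`dyadarc run` writes every intermediate table as CSV, a `summary.json`
with the headline statistics (per-condition and per-compound-category
blast means, T1/T2 negativity, escalation proportions, matching
correlations, the both-vs-neither percent-change contrast), and a run
log.

Simulation configs are YAML files whose keys mirror
`dyadarc.SimulationConfig` (e.g. `n_couples`, `n_rounds`, `condition`,
`decay_rate`, `match_weight`, `seed`). Scoring rules can be overridden
with `--rules rules.yaml` (keys `happiness`, `anger`, `disgust`,
`negative_mode`).

## Data formats

Trial-log CSV schema:

```
couple_id,study,condition,round,winner_id,loser_id,rt_winner_ms,rt_loser_ms,
blast,t_go,t_winner_announced,t_blast_selected,forced_break_s
```

AU-intensity CSV dialect (automated-FACS output): columns
`frame,timestamp,confidence,success,AU01_r…AU45_r` with intensities on
the 0–5 scale; rows with `success=0` are dropped and counted.
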