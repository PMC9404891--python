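# troopcall

Analysis toolkit for studying how acoustic signals coordinate collective
movements in a primate troop, modeled on a provisioned group of Tibetan
macaques (*Macaca thibetana*): 27 focal adults and sub-adults whose group
departures, proximity networks, dominance interactions and movement calls
(coo, leap coo, bark) are observed together.

It is written for behavioral ecologists who have four kinds of field
records — focal proximity sessions, decided aggression–submission bouts,
movement logs with per-individual join times and call counts, and 16-bit
mono WAV recordings of single calls — and want the full analysis chain as
tested, scriptable code. A bundled synthetic-data generator emulates all
four record types with known ground truth, so every stage can be exercised
and validated without any field data.

## What it computes

**Acoustics.** From each call recording, the seven standard parameters:
duration, mean/min/max of the fundamental-frequency (f0) contour, and
mean/min/max frame intensity in dB (full-scale sine ≡ 96 dB). f0 is
tracked by windowed normalized autocorrelation (Gaussian window, 30 ms
frames, 10 ms hop) with sub-harmonic rejection and parabolic lag
interpolation. Calls are assigned to the nearest type profile by
per-feature-standardized Euclidean distance.

**Social metrics.** The dyadic association index
`DAI = D_ab / (D_a + D_b − D_ab)` from 1 m-proximity durations (a
Jaccard-style ratio of joint to combined focal time); eigenvector
centrality of the DAI network by shifted power iteration; David's Score
`DS = w + w2 − l − l2` from dyadic win proportions (raw `P_ij` or the
chance-corrected `D_ij` variant); and matrilineal relative counts.

**Movement analytics.** Segmentation of a join stream into departure
events (closed after 5 min without a new joiner; successful at ≥ 3
participants), initiator/follower displacement rules (over 10 m within
30 s; over 5 m within 45°), the joining-order index
`1 − (I − 1)/(N − 1)` (1 = first, 0 = last), and vocal/non-vocal event
tallies with per-individual vocal rates.

**Statistics.** Mann–Whitney U (exact enumeration for small tie-free
samples, tie- and continuity-corrected normal approximation otherwise),
Spearman rank correlation, and a zero-inflated Poisson (ZIP) regression
of per-individual call counts on sex, centrality, rank and relatives —
a statsmodels-style `VocalCountModel` whose `fit()` returns a results
object with Wald z inference and a `summary()` table.

## Worked example

```python
from troopcall import (TroopConfig, make_roster, simulate_proximity,
                       compute_dai, eigenvector_centrality,
                       paper_tally_events, vocal_summary,
                       synthesize_call, extract_features, classify_call)

cfg = TroopConfig(seed=1)            # 27 focal animals, 12 M / 15 F
troop = make_roster(cfg)
dai = compute_dai(simulate_proximity(troop, cfg), troop)
cent = eigenvector_centrality(dai)

summary = vocal_summary(paper_tally_events(troop, seed=1))
print(summary.n_events, summary.n_vocal, summary.pct_vocal)
# 132 52 39.4

feats = extract_features(synthesize_call("coo"))
print(round(feats.duration, 2), round(feats.mean_f0, 1))
# 0.23 282.0
print(classify_call(feats)[0])
# coo
```

The tally line says: of 132 successful group movements, 52 (39.4%)
involved vocalization. The coo synthesized at its type centroid measures
back at 0.23 s duration with a 282 Hz mean fundamental — the published
centroid — and classifies as a coo.

The same chain is available from a shell:

```sh
troopcall simulate --out run/ --seed 1 --preset paper_tally
troopcall run --config cfg.toml        # full pipeline + report.md
```

`report.md` contains the call-type feature table, the movement tallies,
the vocal-vs-silent participant comparison (Mann–Whitney), the joining
order / vocal rate correlation (Spearman), and the count-model
coefficient table.

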