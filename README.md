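# infoflow

Who leads, who follows, and who explores when homing pigeons fly in pairs?

`infoflow` quantifies moment-to-moment leadership and the
exploration–exploitation balance in paired homing-pigeon GPS tracks. It is
aimed at behavioural ecologists working with transmission-chain release
designs: an experienced bird (E) and a naive bird (N) repeatedly fly home
together, and at the end of each 12-release generation the experienced bird
is replaced by a fresh naive one. The package also ships a paired
correlated-random-walk simulator with a latent leader, so every stage of
the analysis can be validated against known ground truth without any field
data.

## The measures

Each 5 Hz track is reduced to a binary symbol stream of clockwise (0) /
counterclockwise (1) rotations, from the sign of the cross product between
consecutive motion vectors. Influence within a pair is then measured by
**transfer entropy**: with `N_{i+1}` the naive bird's next rotation,
`N^(k)` its k-sample history and `E_i` the experienced bird's current
rotation,

    TE(E→N) = H(N_{i+1} | N^(k)) − H(N_{i+1} | N^(k), E_i)      [bits]

estimated per flight by plug-in (empirical-frequency) probabilities. The
per-transition log-ratio whose average is TE — the **local transfer
entropy** — can be signed, and binned against the signed front/back
distance `d_EN` (the E−N separation projected on the pair's mean direction
of motion) it reveals whether the bird flying in front is the one driving
the pair. Significance comes from a **surrogate** null: re-pairing birds
that never flew together. **Exploration** is any flight segment farther
than 300 m (point-to-point) from the baseline route — the previous release,
or the last release of the previous generation — and leadership within
exploration/exploitation phases and at phase transitions is attributed to
the front bird.

## Worked example

```python
from infoflow import (SimConfig, simulate_pair_flight, pair_te,
                      net_predictive_power)

cfg = SimConfig(n_steps=20_000, w_couple=0.9, tau=1, q_switch=0.0,
                sigma_heading=0.3, alpha_attract=0.1, beta_home=0.05,
                home=(500_000.0, 0.0), seed=1)
pf, truth = simulate_pair_flight(cfg)      # E is the latent leader throughout
res_en, res_ne = pair_te(pf, k=10)
print(res_en.summary())
print(f"net predictive power: {net_predictive_power(res_en, res_ne):+.1f} %")
```

prints

```
Transfer entropy (plug-in, binary rotations)
=============================================
direction                        E -> N
sampling period [s]              0.2
history length k                 10
transitions counted              19988
H(next | past k) [bits]          0.9202
H(next | past k, source) [bits]  0.7647
transfer entropy [bits]          0.1555
predictive power [%]             16.90
net predictive power: +12.7 %
```

The leader explains ~17 % of the follower's otherwise-unpredicted rotation
choices, and the net predictive power is strongly positive — the estimator
recovers the direction of the latent coupling. On an uncoupled pair both
numbers collapse to ≈ 0.

The full pipeline (ingest → filter → encode → TE → surrogates → leadership
→ exploration labelling → trend fits) runs from one config:

```bash
infoflow run --config analysis.yaml     # or: infoflow simulate / te / ingest
```

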