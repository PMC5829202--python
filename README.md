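# shoalkit

Analysis toolkit for the collective behaviour of small fish shoals tracked
in circular arenas: trajectory-derived group metrics, spatial density
summaries, and Bayesian variance-partitioning estimates of group-level and
individual-level behavioural repeatability — bundled with an agent-based
shoal simulator so the whole inference chain can be exercised and validated
without any raw video data.

## Who this is for

Behavioural ecologists studying *collective personality*: do randomly
composed animal groups differ consistently from one another — in how fast
they move, how tightly they shoal, how strongly they align, and how clearly
they divide into leaders and followers — and do those differences persist
across ecological contexts (an open arena, an arena with food patches, an
arena with food and plant cover)?

## The measures

From per-frame 2-D positions `p_i(t)` (mm, 24 frames/s) of the `n` members
of a group, after Savitzky–Golay smoothing (15-frame window, cubic):

- **centroid** `c(t) = (1/n) Σ_i p_i(t)`;
- **speed** `s_i(t) = ‖p_i(t+1) − p_i(t)‖ · fps` (cm/s);
- **cohesion** `d_i(t) = ‖p_i(t) − c(t)‖` (cm), distance to the centroid;
- **polarization** `P(t) = ‖Σ_i u_i(t)‖ / n`, the order parameter over unit
  headings `u_i(t)`, 0 = headings cancel, 1 = perfect alignment;
- **leadership** — the proportion of frames a fish is strictly in front of
  the centroid along the centroid's direction of travel; its population
  variance across members is the group's *leadership structure*.

Per-trial responses (median speed, mean centre distance, front proportion
per fish; median polarization and leadership variance per group) feed
Gaussian random-intercept mixed models estimated by a Gibbs sampler,

```
y = Xβ + u_group + u_individual + e,
u_group ~ N(0, V_group),  u_individual ~ N(0, V_id),  e ~ N(0, V_res),
```

with inverse-gamma(0.001, 0.001) priors on the variances and a diffuse
normal prior on β. Consistency repeatability is the intraclass correlation

```
R_C = V_level / (V_group + V_id + V_res)
```

computed per posterior draw and summarised by its mean and equal-tailed
95% credibility interval.

## Worked example

```python
from shoalkit import (PipelineConfig, run_pipeline, compute_repeatability)

# Published across-context variance components for group speed
r = compute_repeatability(v_group=0.85, v_id=0.00, v_res=0.87)
print(round(r.r_group, 2), round(r.r_id, 2))   # -> 0.49 0.0

# Full synthetic experiment: 4 groups of 5 fish through open / foraging /
# cover contexts, metrics, density maps and repeatability models
cfg = PipelineConfig(out_dir="results/demo", seed=7, n_groups=4)
cfg.sim.durations_s = {"open": 30.0, "foraging": 45.0, "cover": 30.0}
cfg.mcmc.chains, cfg.mcmc.iters, cfg.mcmc.burnin, cfg.mcmc.thin = 2, 2000, 400, 4
res = run_pipeline(cfg)
print(res.across_context[["response", "level", "r_c", "r_c_lo", "r_c_hi", "significant"]])
```

prints (abridged):

```
               response       level       r_c    r_c_lo    r_c_hi  significant
0                 speed       group  0.707791  0.382543  0.964486         True
3          polarization       group  0.424678  0.094763  0.865680         True
4  leadership_structure       group  0.705540  0.283363  0.970861         True
```

Group preferred-speed heterogeneity is injected by the simulator
(among-group SD 0.8 cm/s), so the group-level repeatability of speed is
large and its CI excludes zero, while individual-level speed repeatability
stays near zero — members of a shoal conform in speed. The same pipeline
writes per-trial metric tables, context-effect tables with CI-overlap
verdicts, relative neighbour-position maps (in body lengths) and
speed–polarization density maps under `results/demo/`.

A `shoalkit` command-line tool exposes the stages individually
(`simulate`, `metrics`, `density`, `repeatability`, `pipeline`, `report`).

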