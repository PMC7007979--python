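# lionwelfare

Multi-index behavioural welfare assessment for captive lions (and other
zoo-housed felids): a tested pipeline from instantaneous-scan observation
records, keeper trait ratings and novel-object trial logs to four
per-subject welfare indices, bold/shy personality classification, and the
group-comparison / correlation / regression statistics used to relate
welfare to personality, rearing history, sex and social grouping.  A
synthetic-study generator with known ground truth makes every stage
testable without raw observation data.

## Who this is for

Zoo researchers and welfare scientists running scan-sampling studies of
captive carnivores who want a reproducible, scriptable alternative to
spreadsheet workflows: validated CSV schemas in, a fitted results object
and report tables out.

## The indices and statistics

For each subject, pooled over all one-minute instantaneous scans:

* **Enclosure use — spread of participation index (SPI)**

  SPI = Σ|f_o − f_e| / (2 (N − f_e,min))

  where f_o and f_e are the observed and area-expected scan frequencies
  per enclosure zone (default: ten equal zones), N the total scans, and
  f_e,min the expected frequency of the smallest zone.  SPI = 0 is
  perfectly even zone use; SPI = 1 is total confinement to one zone.

* **Behaviour diversity — Shannon–Weiner index (SWI)**

  H = −Σ p_i ln p_i  (nats)

  over the subject's pooled species-typical behaviour frequencies
  (states plus discrete events; stereotypies excluded).

* **Aberrant repetitive behaviour (ARB %)** — the percentage of scans
  inside stereotypy bouts: maximal runs of one ARB-class behaviour
  (pacing, swaying, head bobbing, nose rubbing) over ≥ 5 consecutive
  recorded minutes, with runs carrying a context flag (pre-feeding,
  keeper activity, conspecific interaction) excluded as displacement
  behaviour.

* **Novel-object latency** — seconds to first approach, censored at the
  600 s test length, averaged over repeated trials; failing to approach
  within 300 s flags the trial as behaviourally shy.

Personality: three keepers rate each subject 1–9 on ten bold and ten shy
trait adjectives; scores are averaged over raters then traits, and a
subject is bold iff mean bold > 7 and mean shy ≤ 7 (mirrored for shy).
Agreement is quantified with Cronbach's alpha (raters as items), and
labels are validated against latency and the % of bold-class focal
behaviour, with a repeat session screening for trait consistency.

Statistics: Shapiro–Wilk/Levene screening; pooled-variance Student
t-tests (Welch available) for SPI/SWI/ARB and two-sample
Kolmogorov–Smirnov tests (z = D·√(n₁n₂/(n₁+n₂))) for latency; Cohen's d
standardised by the root-mean-square of the two group SDs; pairwise
Pearson correlations; and an OLS regression of diversity on stereotypy
level and SPI with VIF and Durbin–Watson diagnostics.

## Worked example

Generate a synthetic study at the default conditions (35 subjects with
the study population's bold/shy × captive/wild × sex × housing structure)
and fit it:

```python
from lionwelfare import WelfareStudy, GeneratorConfig
from lionwelfare.simulate import generate_study

bundle = generate_study(GeneratorConfig(sessions_per_subject=12), seed=1,
                        out_dir="demo_study")
results = WelfareStudy.from_dir("demo_study").fit()
print(results.summary())
```

prints (abridged):

```
Welfare study summary (35 subjects analysed, 0 excluded by consistency screen)
Inter-rater reliability (Cronbach's alpha): 0.977 over 3 raters

Group comparisons (welfare index by factor):
     factor       index      group_a    summary_a  group_b    summary_b     test  statistic   df            p  cohens_d
personality         spi         bold  0.52 ± 0.11      shy  0.72 ± 0.13 pooled_t     4.8183 33.0 3.147595e-05  1.635826
personality         swi         bold  1.20 ± 0.30      shy  0.82 ± 0.36 pooled_t     3.4425 33.0 1.584776e-03  1.164155
personality arb_percent         bold  7.18 ± 3.72      shy 18.46 ± 5.20 pooled_t     7.4902 33.0 1.303443e-08  2.493924
personality   latency_s         bold 11.14 ± 6.89      shy 99.26 ± 19.74      ks     2.8983  NaN 1.011306e-07  5.959950
...
Diversity regression: swi = 1.792 + (-1.105) x spi + (-0.007) x arb_percent
  R^2 = 0.299, F(2, 32) = 6.84, p = 0.0034, DW = 2.06
```

Reading this: bold subjects used their enclosures more evenly (lower
SPI), showed a richer repertoire (higher SWI), stereotyped less and
approached novel objects faster than shy subjects — the group structure
the generator plants and the pipeline recovers.  `results.save("out/")`
writes `profiles.csv`, `indices.csv`, `comparisons.csv`,
`correlations.csv`, `regression.json` and `manifest.json`.

The same pipeline runs from a shell:

```bash
lionwelfare simulate --seed 1 --out demo_study --sessions 12
lionwelfare report --input demo_study --out demo_report
```

For real data, point `WelfareStudy.from_dir` (or the `indices`,
`personality` and `compare` subcommands) at your own CSVs following the
documented schemas (`scans.csv`: subject_id, session_id, time_block,
minute_index, behaviour, zone_id, context; see `docs/methods.md`).

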