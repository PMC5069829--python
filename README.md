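# healthineq

Summary measures of health inequality computed from disaggregated indicator
data, with 95% confidence intervals and table views for exploring inequality
within a setting and benchmarking it between settings.

`healthineq` is aimed at analysts who monitor health inequalities from
pre-aggregated survey tables: one row per (setting, survey source, year,
indicator, inequality dimension, population subgroup), carrying the subgroup
estimate, its standard error and the subgroup's population share. Typical
inputs are reproductive, maternal, newborn and child health indicators
disaggregated by economic status (wealth quintiles), education, place of
residence, sex, or subnational region.

## The measures

For a stratum with subgroup estimates $y_j$, population shares $p_j$
($\sum_j p_j = 1$) and national average $\mu = \sum_j p_j y_j$, the package
computes 15 summary measures — 7 absolute, 8 relative:

| id | measure | formula |
|----|---------|---------|
| ACI | absolute concentration index | $\sum_j p_j (2X_j - 1)\, y_j$ |
| BGV | between-group variance | $\sum_j p_j (y_j - \mu)^2$ |
| D | difference | $y_{high} - y_{low}$ |
| MDB | mean difference from best-performing subgroup | $\sum_j p_j \lvert y_j - y_{ref} \rvert$ |
| MDM | mean difference from mean | $\sum_j p_j \lvert y_j - \mu \rvert$ |
| PAR | population attributable risk | $y_{ref} - \mu$ |
| SII | slope index of inequality | $v_1 - v_0$ (favourable), $v_0 - v_1$ (adverse) |
| IDIS | index of disparity | $\frac{1}{n}\,\frac{\sum_j \lvert y_j - \mu\rvert}{\mu} \times 100$ |
| KMI | Kunst–Mackenbach index | $v_1 / v_0$ (favourable), $v_0 / v_1$ (adverse) |
| MLD | mean log deviation | $\sum_j p_j \left(-\ln \frac{y_j}{\mu}\right) \times 1000$ |
| PAF | population attributable fraction | $\mathrm{PAR}/\mu \times 100$ |
| R | ratio | $y_{high} / y_{low}$ |
| RCI | relative concentration index | $\mathrm{ACI}/\mu \times 100$ |
| RII | relative index of inequality | $\mathrm{SII}/\mu$ |
| TI | Theil index | $\sum_j p_j \frac{y_j}{\mu} \ln \frac{y_j}{\mu} \times 1000$ |

$X_j$ is the relative rank of subgroup $j$ — the midpoint of its cumulative
population-share interval when subgroups are ordered from most disadvantaged
to most advantaged — and $v_0$, $v_1$ are the predicted values at ranks 0 and
1 of a weighted least-squares regression of $y_j$ on $X_j$ (weights $p_j$).
Which measures apply depends on the dimension: ordered dimensions (wealth,
education) admit 9 measures, binary dimensions (residence, sex) 4, and
unordered dimensions with many subgroups (region) 10.

Confidence intervals are analytic for D and R and parametric-bootstrap
(percentile, Normal resampling of subgroup estimates with their stated
standard errors) for the other 13 measures; see `docs/methods.md`.

## Data schema

Delimited text (comma or tab) with a lower-case header. Required columns:
`setting, source, year, indicator_id, dimension, subgroup, estimate,
population_share`. Optional: `se`, `subgroup_order` (1 = most disadvantaged;
required for ordered dimensions), `is_reference`, `income_group`, `region`.
Synonymous headers can be mapped with `read_dataset(..., header_map=...)`.
Dimension kinds and indicator direction (favourable/adverse) come from a
YAML config (`load_config`); shipped defaults cover economic status,
education, place of residence, sex and subnational region.

## Worked example

Generate a synthetic dataset with known inequality structure and compute
wealth-related summary measures for one setting's latest survey:

```
$ healthineq fixtures --out demo.csv --settings 4 --year 2007 --year 2012 --seed 7
wrote 192 records across 48 strata to demo.csv

$ healthineq summary demo.csv --setting "setting 01" --indicator cov_a \
    --dimension "economic status" --latest --ci --seed 11 --decimals 2
setting,source,year,indicator_id,dimension,measure,estimate,ci_lower,ci_upper,note
setting 01,DHS,2012,cov_a,economic status,ACI,-2.95,-3.79,-2.05,
setting 01,DHS,2012,cov_a,economic status,D,-13.58,-18.83,-8.34,
setting 01,DHS,2012,cov_a,economic status,PAR,-5.15,-8.42,-1.6,reference subgroup: quintile 5 (richest)
setting 01,DHS,2012,cov_a,economic status,SII,-18.66,-24.0,-13.0,
setting 01,DHS,2012,cov_a,economic status,KMI,0.5,0.39,0.62,
setting 01,DHS,2012,cov_a,economic status,PAF,-18.49,-30.29,-5.74,reference subgroup: quintile 5 (richest)
setting 01,DHS,2012,cov_a,economic status,R,0.63,0.52,0.76,
setting 01,DHS,2012,cov_a,economic status,RCI,-10.57,-13.93,-7.3,
setting 01,DHS,2012,cov_a,economic status,RII,-0.67,-0.88,-0.46,
```

For this stratum the coverage indicator is *higher among the poorest*: the
slope index of inequality (SII = −18.66, 95% CI −24.0 to −13.0) says
predicted coverage drops by about 19 percentage points from the bottom to
the top of the wealth distribution, the richest-vs-poorest difference is
−13.6 points (D), and the negative concentration indices (ACI, RCI) confirm
concentration among the disadvantaged. KMI and R below 1 carry the same
message on the ratio scale.

Benchmarking against low- and lower-middle-income comparators with surveys
between 2002 and 2012 (reference year 2007, range 5):

```
$ healthineq compare demo.csv --setting "setting 01" --year 2007 --range 5 \
    --indicator cov_a --dimension "economic status" --measure SII \
    --income-group "low income" --income-group "lower middle income"
setting,role,income_group,region,year,setting_average,measure,estimate,ci_lower,ci_upper
setting 01,reference,low income,african region,2007,36.159575956554015,SII,-8.917131323589146,,
setting 02,comparator,lower middle income,region of the americas,2007,62.0075649674366,SII,24.34747881829069,,
```

The same operations are available as a library (`read_dataset`,
`compute_all_measures`, `with_ci`, `summary_table`, `benchmark_table`, ...):

```python
import healthineq as hq

ds = hq.read_dataset("demo.csv")
sl = ds.get_slice(("setting 01", "DHS", 2012, "cov_a", "economic status"))
for res in hq.all_measures_with_ci(sl, hq.BootstrapConfig(seed=11)):
    print(res.measure_id, res.estimate, res.ci_lower, res.ci_upper)
```

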