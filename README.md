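# coastsqueeze

Quantify **coastal squeeze**: how close human infrastructure stands to
sandy shorelines, and how much room that leaves coastal ecosystems to
retreat as seas rise.

Sandy coasts naturally extend kilometres inland through beaches, dunes
and back-barrier habitats. Buildings and paved roads truncate that
gradient from the landward side while sea-level rise consumes it from
the seaward side. This package implements a transect-based accounting of
that squeeze for coastal ecologists, conservation planners and
geospatial analysts:

1. **Transects** — fixed-length (25 km) lines cast perpendicular to the
   shoreline at 1-km interspacing along sandy segments.
2. **Widths** — per transect, the distance to the first structure:
   the *infrastructure-free width* `w_all` (buildings, freeways, car
   roads, paved paths) and the *heavy* variant `w_heavy` (buildings and
   freeways only), with explicit censoring at the transect length.
3. **Natural obstructions** — transects limited before any structure by
   cliffs (maximum seaward slope > 34°, the angle of repose of dry
   sand), by re-crossing the shoreline (narrow strips, islands), or
   lying beyond the 60°N validity limit of coastal elevation models, are
   excluded.
4. **Summaries** — medians, 75th percentiles and below-threshold
   fractions (e.g. share of shores with < 100 m free space) globally and
   by country, continent or latitude band.
5. **Drivers** — country-level OLS: median width ~ log₁₀(coastal
   population density) + log₁₀(GDP per capita).
6. **Protection** — Wilcoxon rank-sum comparison of protected
   (protected-area polygon within the first 2 km) vs unprotected shores,
   and a Kruskal-Wallis + Bonferroni-posthoc comparison across the four
   urban(≥ 300 /km²)/rural × protected/unprotected groups.
7. **Sea-level rise** — nearest retreat projection within 0.05°
   (RCP 4.5 / 8.5, 2100); a transect whose width minus retreat is ≤ 0
   loses all of its infrastructure-free space.

Because the real global inputs are not reproducible at desk scale, the
package ships a first-class synthetic-world generator
(`coastsqueeze.synthetic_world`) producing coastlines, infrastructure,
elevation and population rasters, protected areas and retreat fields
with per-transect ground truth known by construction — the basis of the
test suite. See `docs/methods.md` for the model, conventions and what
synthetic validation does and does not show.

## Worked example

```python
import coastsqueeze as cs

world = cs.generate_world(cs.WorldSpec(seed=7, shore_length_km=200.0))
result = cs.run_world(world)
print(result.summary_global.round(3).to_string(index=False))
```

```
 group   n  median_m  median_is_lower_bound    p75_m  frac_below_100m  frac_below_300m
global 198   508.249                  False 1522.331            0.111            0.298
```

201 transects were cast along 200 km of sandy coast; 3 were excluded as
cliff-limited, leaving n = 198. Half of the remaining shore has less
than ~508 m of infrastructure-free space, 11% less than 100 m and 30%
less than 300 m — widths below ~300 m are too narrow for natural dune
development, so those shores have lost their natural flood-defence
buffer.

```python
w, k = result.wilcoxon, result.kruskal
print(f"protected vs non-protected: Z = {w.statistic:.2f}, p = {w.p_value:.2e}")
print(f"group medians (m): protected {w.group_medians[0]:.0f}, "
      f"non-protected {w.group_medians[1]:.0f}")
print(f"Kruskal-Wallis: chi2 = {k.statistic:.1f}, df = {k.df}, p = {k.p_value:.2e}")
print(result.exposure.round(3).to_string(index=False))
```

```
protected vs non-protected: Z = 4.73, p = 2.24e-06
group medians (m): protected 1528, non-protected 419
Kruskal-Wallis: chi2 = 24.2, df = 3, p = 2.23e-05
 group  n_matched  n_unmatched  frac_lost_rcp45  frac_lost_rcp85
global        198            0            0.177            0.222
```

Protected shores keep a ~3.6× wider infrastructure-free zone here, and
the projected 2100 retreats would fully consume the free space of 18%
(RCP 4.5) to 22% (RCP 8.5) of these transects.

The same stages run from the shell (`coastsqueeze --help`): `simulate`,
`transects`, `measure`, `exclude`, `stats`, `regress`, `protect`, `slr`,
exchanging files so each stage can be re-run independently.

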