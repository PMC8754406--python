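# pexsite

Quantitative machinery for detecting organelle-associated translation, built
around the case of yeast peroxisomes. Peroxisomal membrane proteins are
hydrophobic and aggregation-prone; one route for getting them safely into the
membrane is localized translation — ribosomes sitting on the organelle
surface, translating the right transcripts in place. Demonstrating that
requires three independent, quantitative measurements, and this package
implements all three as a tested, reusable pipeline:

1. **Ribosome exclusion-zone (REZ) profiling** (`pexsite.profiler`) — given a
   spherical membrane model and picked ribosome centroids from an electron
   tomogram, compute ribosome density as a function of distance from the
   membrane (concentric 5-px shells, ribosomes projected as 9-px spheres,
   density = occupied fraction of each shell), average profiles across
   organelles, estimate the width of the depleted zone next to the membrane,
   and count membrane-proximal ribosomes (surface distance < 20 nm).
2. **Proximity-specific ribosome-profiling enrichment** (`pexsite.enrichment`)
   — P-site assignment at a 15-nt offset from the footprint 3′ end, counting
   within countable CDS (same-strand overlaps excluded), reads-per-million
   densities, per-gene log2(pulldown/input), input-coverage and annotation
   filters, z-normalization, and threshold calling with a dual-bait
   intersection rule, plus two-organelle comparison.
3. **Spot colocalization statistics** (`pexsite.coloc`) — the percentage of
   peroxisomes with an mRNA spot within a distance threshold in two-channel
   smFISH-style fields, with a within-field permutation baseline and group
   comparisons (t test / Mann–Whitney).

Every stage is paired with a synthetic generator (`pexsite.synth`) that
produces data with known ground truth — planted exclusion zones and proximal
ribosomes, planted enrichment effects, planted colocalization probabilities —
so the whole pipeline is testable end to end without any external data.

Audience: microscopists and genomicists building organelle-proximity analyses,
and anyone needing a worked, oracle-tested reference for shell-mask density
profiling, footprint enrichment calling, or colocalization statistics.

## Worked example

Generate the default 51-organelle scene ensemble (sphere radii 25–100 nm,
cytosolic ribosomes at the calibrated density behind a one-ribosome-diameter
exclusion zone, 1–3 planted proximal ribosomes each) and measure it:

```python
import numpy as np
from pexsite.synth import sample_default_scenes
from pexsite.profiler import (ShellSpec, shell_density_profile,
                              average_profiles, estimate_rez_width,
                              count_proximal)

scenes = sample_default_scenes(51, seed=1)
spec = ShellSpec()  # 20 shells x 5 px, 9-px ribosome projection
profiles = [shell_density_profile(s.membrane, s.ribosomes, spec, crop=s.crop)
            for s in scenes]
avg = average_profiles(profiles)
print(f"REZ width: {estimate_rez_width(avg):.1f} nm")
prox = [count_proximal(s.membrane, s.ribosomes, threshold_nm=20.0)
        for s in scenes]
print(f"proximal ribosomes per organelle: {np.mean(prox):.2f} "
      f"(range {min(prox)}-{max(prox)})")
print(f"ribosomes per crop: {np.mean([len(s.ribosomes) for s in scenes]):.0f}")
```

prints

```
REZ width: 18.4 nm
proximal ribosomes per organelle: 2.12 (range 1-3)
ribosomes per crop: 300
```

The 18.4-nm width recovers the planted 20.9-nm exclusion half-width to within
one shell (5.8 nm): a membrane surrounded by a ribosome-free gap of roughly
one ribosome diameter. The proximal count — the handful of ribosomes that
cross the zone — is recovered exactly as planted, independent of organelle
size.

The same stages are available from the shell:

```sh
pexsite simulate-tomo --seed 1 --n-scenes 51 --out-dir scenes/
pexsite prez --scenes scenes/scene000.json --scenes scenes/scene001.json \
    --out-dir prez_out/
pexsite simulate-ribo --seed 1 --out-dir ribo/
pexsite enrich --genes ribo/genes.gff3 --flags ribo/gene_flags.tsv \
    --input ribo/bait1_input.tsv --pulldown ribo/bait1_pulldown.tsv \
    --input ribo/bait2_input.tsv --pulldown ribo/bait2_pulldown.tsv \
    --out-dir enrich_out/
pexsite simulate-spots --seed 1 --out-dir spots/
pexsite coloc --spots spots/spots.tsv --masks spots/cell_masks.json \
    --seed 1 --out-dir coloc_out/
```

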