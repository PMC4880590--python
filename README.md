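# leafspad

**Where on a rice leaf should the SPAD meter go?**

Chlorophyll is unevenly distributed along a rice leaf blade: SPAD values
rise from the base, peak at 50–60 % of the blade length, and fall toward
the tip. A single hand-held SPAD chlorophyll-meter reading therefore
depends strongly on where it is taken, which matters for anyone using SPAD
readings to diagnose crop nitrogen status. `leafspad` implements the full
image-based analysis that answers this question, from a flatbed scan of a
leaf blade to a recommended measurement position.

## The method

1. **Scan normalization.** Black/white cardboard reflectance standards in
   each scan are mapped per channel to DN 0 and 255, making digital
   numbers (DN) comparable across scans.
2. **Calibration.** The red-band DN of scanned leaf tissue is linearly
   related to the SPAD reading; the shipped constant is

   $$\mathrm{SPAD} = -0.2509\,R + 52.735 \qquad (r^2 = 0.851,\ n = 39)$$

   and a local calibration can be refitted from `(dn, spad)` pairs.
3. **Chlorophyll profile.** A concave quadratic
   $\mathrm{SPAD}(L) = a_2 L^2 + a_1 L + a_0$ is fitted to SPAD against
   distance $L$ (cm) from the leaf base.
4. **Representative value (the calculus method).** The blade is cut into
   $k = 10$ equal-length parts; each part's area $A_i$ comes from
   numerically integrating the digitized width profile, and the
   area-weighted representative value is

   $$C = \frac{\sum_i A_i\,\mathrm{SPAD}_i}{\sum_i A_i},$$

   compared against the conventional arithmetic mean.
5. **Representative positions and selection.** Solving
   $\mathrm{SPAD}(L) = C$ (or the mean) gives two candidate positions; the
   one lying in the lowest-variance region of the blade (empirically the
   60–80 % band, i.e. near the 2/3 position) is recommended.

A synthetic-leaf generator (silhouette family with a closed-form area,
profile sampling, and a full scanner forward model with reflectance
standards and sensor noise) makes every stage testable end to end without
any field data.

## Worked example

The packaged reference case is one blade under light nitrogen deficiency:
ten per-part SPAD values (base → tip) `35.8, 36.5, 39.2, 40.3, 40.6, 39.8,
41.2, 39.4, 37.1, 34.3` and the fitted profile
$\mathrm{SPAD}(L) = -0.0452 L^2 + 1.1289 L + 33.763$.

```python
from leafspad import representative, synthetic
from leafspad.datasets import REFERENCE_SPAD_PARTS, reference_profile

shape = synthetic.make_leaf_shape(25.2, 1.2, 0.5, 201)
report = representative.positions_report(
    shape, reference_profile(), REFERENCE_SPAD_PARTS)
print(report.summary())
```

prints

```
Representative SPAD values and positions
  area-weighted C      = 39.33  -> L = 6.76, 18.21 cm
  conventional mean    = 38.42  -> L = 5.21, 19.76 cm
  proportional (C)     = 0.27, 0.72
  proportional (mean)  = 0.21, 0.78
```

The conventional mean of the ten parts is **38.42**, attained at **5.21**
and **19.76 cm** from the base (~1/5 and ~4/5 of the blade). Weighting by
part area shifts the representative value up (the wide mid-blade carries
more leaf than the narrow ends) and pulls both candidate positions inward
— here to 27 % and 72 % of the blade for this synthetic silhouette. The
distal candidate lands in the low-variance 60–80 % band, which is why the
2/3 position is the recommended place to clip the meter.

The same pipeline is scriptable from the shell:

```sh
leafspad --seed 42 simulate --length 20 --out demo/        # synthetic scan
leafspad process --scan demo/scan.png --out demo_proc/     # parts.csv + shape.csv
leafspad run --scan demo/scan.png --scan demo2/scan.png --out report/
```

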