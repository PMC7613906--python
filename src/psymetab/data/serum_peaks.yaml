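# Serum 1H-NMR peak library (700 MHz conventions).
#
# Positions and multiplicities follow standard serum/plasma assignments
# (HMDB-style literature values).  Heights are relative abundances on an
# arbitrary common scale; `linewidth` is the Lorentzian half-width at half
# maximum in ppm.  `class: broad` marks lipoprotein/macromolecule envelopes,
# which are modelled as single wide Lorentzians and are exempt from the
# per-spectrum chemical-shift jitter applied to sharp resonances.
#
# Multiplets: `multiplicity` n expands to n lines spaced by j_hz (converted to
# ppm at the configured spectrometer frequency) with binomial intensity
# pattern; the tallest line gets the stated height.
spectrometer_frequency_mhz: 700.0
metabolites:
  - name: lipid_ch3            # -CH3 terminal methyl, lipoproteins
    class: broad
    linewidth: 0.015
    multiplets:
      - {center: 0.86, multiplicity: 1, j_hz: 0.0, height: 1.0}
  - name: lipid_ch2            # (-CH2-)n methylene envelope
    class: broad
    linewidth: 0.015
    multiplets:
      - {center: 1.26, multiplicity: 1, j_hz: 0.0, height: 1.6}
  - name: lipid_allylic        # =CH-CH2-CH2-
    class: broad
    linewidth: 0.015
    multiplets:
      - {center: 2.02, multiplicity: 1, j_hz: 0.0, height: 0.5}
  - name: lipid_unsaturated    # olefinic =CH-
    class: broad
    linewidth: 0.015
    multiplets:
      - {center: 5.30, multiplicity: 1, j_hz: 0.0, height: 0.45}
  - name: glyca                # N-acetyl glycoprotein composite
    class: broad
    linewidth: 0.012
    multiplets:
      - {center: 2.04, multiplicity: 1, j_hz: 0.0, height: 0.25}
  - name: leucine
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 0.95, multiplicity: 2, j_hz: 6.5, height: 0.40}
  - name: isoleucine
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 0.93, multiplicity: 3, j_hz: 7.4, height: 0.30}
      - {center: 1.00, multiplicity: 2, j_hz: 7.0, height: 0.30}
  - name: valine
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 0.98, multiplicity: 2, j_hz: 7.0, height: 0.40}
      - {center: 1.04, multiplicity: 2, j_hz: 7.0, height: 0.40}
  - name: 3-hydroxybutyrate
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 1.20, multiplicity: 2, j_hz: 6.3, height: 0.25}
      - {center: 2.31, multiplicity: 2, j_hz: 7.0, height: 0.12}
  - name: lactate
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 1.33, multiplicity: 2, j_hz: 7.0, height: 1.20}
      - {center: 4.11, multiplicity: 4, j_hz: 7.0, height: 0.30}
  - name: alanine
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 1.48, multiplicity: 2, j_hz: 7.2, height: 0.50}
  - name: lysine
    class: sharp
    linewidth: 0.0020
    multiplets:
      - {center: 1.72, multiplicity: 3, j_hz: 7.0, height: 0.30}
      - {center: 3.02, multiplicity: 3, j_hz: 7.0, height: 0.30}
  - name: acetoacetate
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 2.27, multiplicity: 1, j_hz: 0.0, height: 0.15}
  - name: glutamine
    class: sharp
    linewidth: 0.0020
    multiplets:
      - {center: 2.14, multiplicity: 1, j_hz: 0.0, height: 0.25}
      - {center: 2.45, multiplicity: 1, j_hz: 0.0, height: 0.25}
  - name: citrate
    class: sharp
    linewidth: 0.0020
    multiplets:
      - {center: 2.54, multiplicity: 2, j_hz: 15.0, height: 0.20}
      - {center: 2.66, multiplicity: 2, j_hz: 15.0, height: 0.20}
  - name: creatinine
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 3.04, multiplicity: 1, j_hz: 0.0, height: 0.30}
      - {center: 4.06, multiplicity: 1, j_hz: 0.0, height: 0.20}
  - name: choline             # -N(CH3)3 trimethylamine singlet
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 3.20, multiplicity: 1, j_hz: 0.0, height: 0.50}
  - name: glucose
    class: sharp
    linewidth: 0.0022
    multiplets:
      - {center: 3.24, multiplicity: 1, j_hz: 0.0, height: 0.45}
      - {center: 3.40, multiplicity: 1, j_hz: 0.0, height: 0.55}
      - {center: 3.46, multiplicity: 1, j_hz: 0.0, height: 0.55}
      - {center: 3.53, multiplicity: 1, j_hz: 0.0, height: 0.50}
      - {center: 3.72, multiplicity: 1, j_hz: 0.0, height: 0.60}
      - {center: 3.82, multiplicity: 1, j_hz: 0.0, height: 0.45}
      - {center: 3.89, multiplicity: 1, j_hz: 0.0, height: 0.40}
      - {center: 5.23, multiplicity: 2, j_hz: 3.7, height: 0.35}
  - name: glycine
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 3.56, multiplicity: 1, j_hz: 0.0, height: 0.20}
  - name: myo-inositol
    class: sharp
    linewidth: 0.0020
    multiplets:
      - {center: 3.28, multiplicity: 1, j_hz: 0.0, height: 0.15}
      - {center: 4.06, multiplicity: 1, j_hz: 0.0, height: 0.10}
  - name: urea
    class: broad
    linewidth: 0.012
    multiplets:
      - {center: 5.78, multiplicity: 1, j_hz: 0.0, height: 0.20}
  - name: tyrosine
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 6.90, multiplicity: 2, j_hz: 8.5, height: 0.10}
      - {center: 7.19, multiplicity: 2, j_hz: 8.5, height: 0.10}
  - name: histidine
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 7.08, multiplicity: 1, j_hz: 0.0, height: 0.08}
      - {center: 7.83, multiplicity: 1, j_hz: 0.0, height: 0.08}
  - name: phenylalanine
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 7.33, multiplicity: 1, j_hz: 0.0, height: 0.08}
      - {center: 7.38, multiplicity: 1, j_hz: 0.0, height: 0.10}
      - {center: 7.43, multiplicity: 1, j_hz: 0.0, height: 0.08}
  - name: formate
    class: sharp
    linewidth: 0.0018
    multiplets:
      - {center: 8.45, multiplicity: 1, j_hz: 0.0, height: 0.06}
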