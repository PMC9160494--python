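"""Code alcohol exposure categories and match ICD-10 diagnosis codes.

One unit is 10 g ethanol; moderate = 1-14 units/week, heavy = above the
threshold (14 by default, 21 as a sensitivity). The shipped code sets cover
alcohol-related hospitalisation, alcohol-related death and wholly
alcohol-attributable conditions.
"""

from dfyears import (CodingConfig, categorize3, categorize6, categorize_daily8,
                     icd_expand_range, icd_match, load_codesets, rescale_units)

print("14 units/week  ->", categorize3(14.0), "(the 1-14 band is inclusive)")
print("14.01 units    ->", categorize3(14.01))
print("14 units at 8g ->", categorize3(14.0, CodingConfig(unit_grams=8.0)),
      f"(rescaled to {rescale_units(14.0, 8.0):.1f} 8-gram units)")
print("10 units, binge ->", categorize6(10.0, 1, 0, 1))
print("21 units/week  -> daily-dose category", categorize_daily8(21.0))

codes = load_codesets()
hosp = codes["alcohol_hospitalisation"]
print("\nF10.1 hospitalisation?", icd_match("F10.1", hosp))
print("F10.2 hospitalisation?", icd_match("F10.2", hosp),
      "(only F10.0/F10.1 qualify, not the whole F10 block)")
span = icd_expand_range("S00", "Y91")
print(f"S00-Y91 expands to {len(span)} three-character categories; "
      f"X45 included: {'X45' in span}")
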