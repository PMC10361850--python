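# Registry spelling -> canonical level map, applied case-insensitively on
# read.  Versioned: bump when a registry changes its export vocabulary.
version: 1

year:
  "2017.0": "2017"
  "2018.0": "2018"

age_band:
  "40–49": "40-49"
  "50–59": "50-59"
  "60–69": "60-69"
  "70–79": "70-79"
  "80 +": "80+"
  ">=80": "80+"

histology:
  "ductal carcinoma": "ductal"
  "invasive ductal carcinoma": "ductal"
  "nst": "ductal"
  "lobular carcinoma": "lobular"
  "invasive lobular carcinoma": "lobular"

grade:
  "well differentiated": "well"
  "moderately differentiated": "moderate"
  "poorly differentiated": "poor"
  "grade 1": "well"
  "grade 2": "moderate"
  "grade 3": "poor"
  "gx": "unknown"
  "missing": "unknown"

pt:
  "pTx": "unknown"
  "ptx": "unknown"
  "tx": "unknown"
  "t1": "<2cm"
  "pt1": "<2cm"
  "t2": "2-5cm"
  "pt2": "2-5cm"
  "t3": "5+cm"
  "pt3": "5+cm"
  "2–5cm": "2-5cm"

pn:
  "pnx": "unknown"
  "nx": "unknown"
  "n0": "pN0"
  "pn0": "pN0"
  "0": "pN0"
  "1-3": "pN1-3"
  "1–3": "pN1-3"
  "4+": "pN4+"

her2:
  "neg": "negative"
  "pos": "positive"
  "0-1+": "negative"
  "3+": "positive"
  "2+": "unknown"

er:
  "neg": "negative"
  "pos": "positive"

pr:
  "neg": "negative"
  "pos": "positive"
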