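{
 "version": 1,
 "synthetic": true,
 "note": "Synthetic stand-in suite library: 46 distinct cluster centers in the 7D RNA backbone torsion space, composed from canonical torsion classes; not the published consensus table.",
 "halfwidth": [
  28.0,
  60.0,
  55.0,
  50.0,
  70.0,
  35.0,
  28.0
 ],
 "assignment_threshold": 0.001,
 "suites": [
  {
   "center": [
    81.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    54.0,
    81.0
   ],
   "name": "1a"
  },
  {
   "center": [
    81.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    178.0,
    81.0
   ],
   "name": "S01"
  },
  {
   "center": [
    81.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    -64.0,
    81.0
   ],
   "name": "S02"
  },
  {
   "center": [
    81.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    54.0,
    147.0
   ],
   "name": "S03"
  },
  {
   "center": [
    81.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    178.0,
    147.0
   ],
   "name": "S04"
  },
  {
   "center": [
    81.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    -64.0,
    147.0
   ],
   "name": "S05"
  },
  {
   "center": [
    147.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    54.0,
    81.0
   ],
   "name": "S06"
  },
  {
   "center": [
    147.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    178.0,
    81.0
   ],
   "name": "S07"
  },
  {
   "center": [
    147.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    -64.0,
    81.0
   ],
   "name": "S08"
  },
  {
   "center": [
    147.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    54.0,
    147.0
   ],
   "name": "S09"
  },
  {
   "center": [
    147.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    178.0,
    147.0
   ],
   "name": "S10"
  },
  {
   "center": [
    147.0,
    -148.0,
    -71.0,
    -65.0,
    174.0,
    -64.0,
    147.0
   ],
   "name": "S11"
  },
  {
   "center": [
    81.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    54.0,
    81.0
   ],
   "name": "S12"
  },
  {
   "center": [
    81.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    178.0,
    81.0
   ],
   "name": "S13"
  },
  {
   "center": [
    81.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    -64.0,
    81.0
   ],
   "name": "S14"
  },
  {
   "center": [
    81.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    54.0,
    147.0
   ],
   "name": "S15"
  },
  {
   "center": [
    81.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    178.0,
    147.0
   ],
   "name": "S16"
  },
  {
   "center": [
    81.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    -64.0,
    147.0
   ],
   "name": "S17"
  },
  {
   "center": [
    147.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    54.0,
    81.0
   ],
   "name": "S18"
  },
  {
   "center": [
    147.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    178.0,
    81.0
   ],
   "name": "S19"
  },
  {
   "center": [
    147.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    -64.0,
    81.0
   ],
   "name": "S20"
  },
  {
   "center": [
    147.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    54.0,
    147.0
   ],
   "name": "S21"
  },
  {
   "center": [
    147.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    178.0,
    147.0
   ],
   "name": "S22"
  },
  {
   "center": [
    147.0,
    -133.0,
    -71.0,
    164.0,
    148.0,
    -64.0,
    147.0
   ],
   "name": "S23"
  },
  {
   "center": [
    81.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    54.0,
    81.0
   ],
   "name": "S24"
  },
  {
   "center": [
    81.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    178.0,
    81.0
   ],
   "name": "S25"
  },
  {
   "center": [
    81.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    -64.0,
    81.0
   ],
   "name": "S26"
  },
  {
   "center": [
    81.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    54.0,
    147.0
   ],
   "name": "S27"
  },
  {
   "center": [
    81.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    178.0,
    147.0
   ],
   "name": "S28"
  },
  {
   "center": [
    81.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    -64.0,
    147.0
   ],
   "name": "S29"
  },
  {
   "center": [
    147.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    54.0,
    81.0
   ],
   "name": "S30"
  },
  {
   "center": [
    147.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    178.0,
    81.0
   ],
   "name": "S31"
  },
  {
   "center": [
    147.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    -64.0,
    81.0
   ],
   "name": "S32"
  },
  {
   "center": [
    147.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    54.0,
    147.0
   ],
   "name": "S33"
  },
  {
   "center": [
    147.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    178.0,
    147.0
   ],
   "name": "S34"
  },
  {
   "center": [
    147.0,
    -156.0,
    70.0,
    65.0,
    180.0,
    -64.0,
    147.0
   ],
   "name": "S35"
  },
  {
   "center": [
    81.0,
    -100.0,
    -120.0,
    -110.0,
    90.0,
    54.0,
    81.0
   ],
   "name": "S36"
  },
  {
   "center": [
    81.0,
    -100.0,
    -120.0,
    -110.0,
    90.0,
    178.0,
    81.0
   ],
   "name": "S37"
  },
  {
   "center": [
    81.0,
    -100.0,
    -120.0,
    -110.0,
    90.0,
    -64.0,
    81.0
   ],
   "name": "S38"
  },
  {
   "center": [
    81.0,
    -100.0,
    -120.0,
    -110.0,
    90.0,
    54.0,
    147.0
   ],
   "name": "S39"
  },
  {
   "center": [
    81.0,
    -100.0,
    -120.0,
    -110.0,
    90.0,
    178.0,
    147.0
   ],
   "name": "S40"
  },
  {
   "center": [
    81.0,
    -100.0,
    -120.0,
    -110.0,
    90.0,
    -64.0,
    147.0
   ],
   "name": "S41"
  },
  {
   "center": [
    147.0,
    -100.0,
    -120.0,
    -110.0,
    90.0,
    54.0,
    81.0
   ],
   "name": "S42"
  },
  {
   "center": [
    147.0,
    -100.0,
    -120.0,
    -110.0,
    90.0,
    178.0,
    81.0
   ],
   "name": "S43"
  },
  {
   "center": [
    147.0,
    -100.0,
    -120.0,
    -110.0,
    90.0,
    -64.0,
    81.0
   ],
   "name": "S44"
  },
  {
   "center": [
    147.0,
    -100.0,
    -120.0,
    -110.0,
    90.0,
    54.0,
    147.0
   ],
   "name": "S45"
  }
 ]
}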