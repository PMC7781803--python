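{
  "version": "default-1.0",
  "rules": [
    {"pattern": "qi-deficiency of lung and spleen", "elements": ["qi-deficiency", "lung", "spleen"], "priority": 1},
    {"pattern": "qi-deficiency of lung and kidney", "elements": ["qi-deficiency", "lung", "kidney"], "priority": 2},
    {"pattern": "yin-deficiency of lung", "elements": ["yin-deficiency", "lung"], "priority": 3},
    {"pattern": "wind-cold attacking lung", "elements": ["wind", "cold", "lung"], "priority": 4},
    {"pattern": "wind-heat attacking lung", "elements": ["wind", "heat", "lung"], "priority": 5},
    {"pattern": "cold wheezing", "elements": ["wind", "cold", "phlegm", "lung"], "priority": 6},
    {"pattern": "deficiency of qi and yin", "elements": ["qi-deficiency", "yin-deficiency"], "priority": 7},
    {"pattern": "hot wheezing", "elements": ["wind", "heat", "phlegm", "lung"], "priority": 8},
    {"pattern": "phlegm-heat obstruction in lung", "elements": ["phlegm", "heat", "lung"], "priority": 9},
    {"pattern": "phlegm obstruction in lung", "elements": ["phlegm", "lung"], "priority": 10}
  ]
}
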