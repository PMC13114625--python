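{
 "nodes": [
  "X1",
  "X2",
  "M",
  "Y1",
  "Y2",
  "U"
 ],
 "hidden": [
  "U"
 ],
 "edges": [
  [
   "X1",
   "M"
  ],
  [
   "X2",
   "M"
  ],
  [
   "U",
   "M"
  ],
  [
   "M",
   "Y1"
  ],
  [
   "M",
   "Y2"
  ],
  [
   "U",
   "Y1"
  ],
  [
   "U",
   "Y2"
  ]
 ],
 "arcs": []
}
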