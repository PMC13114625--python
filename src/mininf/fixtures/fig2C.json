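{
 "nodes": [
  "Z",
  "X",
  "Y1",
  "Y2",
  "Y3",
  "W2",
  "W3",
  "U"
 ],
 "hidden": [
  "U"
 ],
 "edges": [
  [
   "Z",
   "X"
  ],
  [
   "Z",
   "W2"
  ],
  [
   "Z",
   "W3"
  ],
  [
   "U",
   "X"
  ],
  [
   "U",
   "Y1"
  ],
  [
   "W2",
   "Y1"
  ],
  [
   "X",
   "Y1"
  ],
  [
   "Y2",
   "W2"
  ],
  [
   "Y3",
   "W3"
  ]
 ],
 "arcs": []
}
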