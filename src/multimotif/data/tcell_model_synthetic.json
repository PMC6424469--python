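{
 "description": "Synthetic early T-cell commitment model: 4 core TFs (PU1, TCF1, GATA3, BCL11B) with an additive Notch drive on TCF1. Constructed by the package's own random search and annealed refinement under the four-ordered-attractor, bifurcation and knockout selection criteria; not transcribed from any publication.",
 "topology": {
  "nodes": [
   "PU1",
   "TCF1",
   "GATA3",
   "BCL11B"
  ],
  "regulations": [
   {
    "source": "PU1",
    "target": "PU1",
    "sign": 1
   },
   {
    "source": "GATA3",
    "target": "PU1",
    "sign": -1
   },
   {
    "source": "BCL11B",
    "target": "PU1",
    "sign": -1
   },
   {
    "source": "PU1",
    "target": "TCF1",
    "sign": -1
   },
   {
    "source": "TCF1",
    "target": "TCF1",
    "sign": 1
   },
   {
    "source": "PU1",
    "target": "GATA3",
    "sign": -1
   },
   {
    "source": "TCF1",
    "target": "GATA3",
    "sign": 1
   },
   {
    "source": "GATA3",
    "target": "GATA3",
    "sign": 1
   },
   {
    "source": "TCF1",
    "target": "BCL11B",
    "sign": 1
   },
   {
    "source": "GATA3",
    "target": "BCL11B",
    "sign": 1
   },
   {
    "source": "BCL11B",
    "target": "BCL11B",
    "sign": 1
   }
  ]
 },
 "parameters": {
  "form": "multiplicative",
  "k0.PU1": 0.3429,
  "k.PU1": 2.2458,
  "rd.PU1": 1.04,
  "k0.TCF1": 0.1687,
  "k.TCF1": 1.9234,
  "rd.TCF1": 1.04,
  "k0.GATA3": 0.0589,
  "k.GATA3": 6.0,
  "rd.GATA3": 1.04,
  "k0.BCL11B": 0.0609,
  "k.BCL11B": 1.5585,
  "rd.BCL11B": 1.04,
  "K.PU1->PU1": 0.6043,
  "n.PU1->PU1": 6.0123,
  "K.GATA3->PU1": 4.5,
  "n.GATA3->PU1": 3.5553,
  "K.BCL11B->PU1": 1.12,
  "n.BCL11B->PU1": 2.6728,
  "K.PU1->TCF1": 3.0468,
  "n.PU1->TCF1": 5.3539,
  "K.TCF1->TCF1": 0.6404,
  "n.TCF1->TCF1": 4.3268,
  "K.PU1->GATA3": 2.8418,
  "n.PU1->GATA3": 3.7697,
  "K.TCF1->GATA3": 2.2,
  "n.TCF1->GATA3": 2.5373,
  "K.GATA3->GATA3": 0.5905,
  "n.GATA3->GATA3": 1.0003,
  "K.TCF1->BCL11B": 0.3307,
  "n.TCF1->BCL11B": 5.1627,
  "K.GATA3->BCL11B": 1.1502,
  "n.GATA3->BCL11B": 7.4385,
  "K.BCL11B->BCL11B": 0.13,
  "n.BCL11B->BCL11B": 3.6765
 },
 "inputs": [
  {
   "signal": "Notch",
   "target": "TCF1",
   "k": 1.6,
   "K": 0.28,
   "n": 3.6174
  }
 ]
}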