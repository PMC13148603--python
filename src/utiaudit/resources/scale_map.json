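{
 "version": "1",
 "components": {
  "blood": {
   "levels": [
    "negative",
    "trace",
    "moderate",
    "large"
   ],
   "dialects": {
    "qualitative": {
     "negative": 0,
     "trace": 1,
     "moderate": 2,
     "large": 3,
     "small": 1,
     "neg": 0
    },
    "semiquantitative": {
     "negative": 0,
     "1+": 1,
     "2+": 2,
     "3+": 3
    },
    "quantitative": {
     "negative": 0,
     "1+": 1,
     "2+": 2,
     "3+": 3
    }
   },
   "render": {
    "qualitative": [
     "negative",
     "trace",
     "moderate",
     "large"
    ],
    "semiquantitative": [
     "negative",
     "1+",
     "2+",
     "3+"
    ],
    "quantitative": [
     "negative",
     "1+",
     "2+",
     "3+"
    ]
   }
  },
  "glucose": {
   "levels": [
    "negative",
    "trace",
    "moderate",
    "large"
   ],
   "dialects": {
    "qualitative": {
     "negative": 0,
     "trace": 1,
     "moderate": 2,
     "large": 3,
     "small": 1,
     "neg": 0
    },
    "semiquantitative": {
     "negative": 0,
     "1+": 1,
     "2+": 2,
     "3+": 3
    },
    "quantitative": {
     "negative": 0,
     "100 mg/dl": 1,
     "250 mg/dl": 2,
     "500 mg/dl": 3
    }
   },
   "render": {
    "qualitative": [
     "negative",
     "trace",
     "moderate",
     "large"
    ],
    "semiquantitative": [
     "negative",
     "1+",
     "2+",
     "3+"
    ],
    "quantitative": [
     "negative",
     "100 mg/dl",
     "250 mg/dl",
     "500 mg/dl"
    ]
   }
  },
  "ketones": {
   "levels": [
    "negative",
    "trace",
    "moderate",
    "large"
   ],
   "dialects": {
    "qualitative": {
     "negative": 0,
     "trace": 1,
     "moderate": 2,
     "large": 3,
     "small": 1,
     "neg": 0
    },
    "semiquantitative": {
     "negative": 0,
     "1+": 1,
     "2+": 2,
     "3+": 3
    },
    "quantitative": {
     "negative": 0,
     "15 mg/dl": 1,
     "40 mg/dl": 2,
     "80 mg/dl": 3
    }
   },
   "render": {
    "qualitative": [
     "negative",
     "trace",
     "moderate",
     "large"
    ],
    "semiquantitative": [
     "negative",
     "1+",
     "2+",
     "3+"
    ],
    "quantitative": [
     "negative",
     "15 mg/dl",
     "40 mg/dl",
     "80 mg/dl"
    ]
   }
  },
  "leukocyte_esterase": {
   "levels": [
    "negative",
    "small",
    "moderate",
    "large"
   ],
   "dialects": {
    "qualitative": {
     "negative": 0,
     "small": 1,
     "moderate": 2,
     "large": 3,
     "trace": 1,
     "neg": 0
    },
    "semiquantitative": {
     "negative": 0,
     "1+": 1,
     "2+": 2,
     "3+": 3
    },
    "quantitative": {
     "negative": 0,
     "1+": 1,
     "2+": 2,
     "3+": 3
    }
   },
   "render": {
    "qualitative": [
     "negative",
     "small",
     "moderate",
     "large"
    ],
    "semiquantitative": [
     "negative",
     "1+",
     "2+",
     "3+"
    ],
    "quantitative": [
     "negative",
     "1+",
     "2+",
     "3+"
    ]
   }
  },
  "nitrites": {
   "levels": [
    "negative",
    "positive"
   ],
   "dialects": {
    "qualitative": {
     "negative": 0,
     "neg": 0,
     "positive": 1,
     "pos": 1
    },
    "semiquantitative": {
     "negative": 0,
     "neg": 0,
     "positive": 1,
     "pos": 1
    },
    "quantitative": {
     "negative": 0,
     "neg": 0,
     "positive": 1,
     "pos": 1
    }
   },
   "render": {
    "qualitative": [
     "negative",
     "positive"
    ],
    "semiquantitative": [
     "negative",
     "positive"
    ],
    "quantitative": [
     "negative",
     "positive"
    ]
   }
  },
  "protein": {
   "levels": [
    "negative",
    "trace",
    "moderate",
    "large"
   ],
   "dialects": {
    "qualitative": {
     "negative": 0,
     "trace": 1,
     "moderate": 2,
     "large": 3,
     "small": 1,
     "neg": 0
    },
    "semiquantitative": {
     "negative": 0,
     "1+": 1,
     "2+": 2,
     "3+": 3
    },
    "quantitative": {
     "negative": 0,
     "30 mg/dl": 1,
     "100 mg/dl": 2,
     "300 mg/dl": 3
    }
   },
   "render": {
    "qualitative": [
     "negative",
     "trace",
     "moderate",
     "large"
    ],
    "semiquantitative": [
     "negative",
     "1+",
     "2+",
     "3+"
    ],
    "quantitative": [
     "negative",
     "30 mg/dl",
     "100 mg/dl",
     "300 mg/dl"
    ]
   }
  },
  "bacteria": {
   "levels": [
    "none",
    "few",
    "moderate",
    "many"
   ],
   "dialects": {
    "qualitative": {
     "none": 0,
     "negative": 0,
     "neg": 0,
     "few": 1,
     "rare": 1,
     "moderate": 2,
     "many": 3,
     "loaded": 3
    },
    "semiquantitative": {
     "negative": 0,
     "1+": 1,
     "2+": 2,
     "3+": 3,
     "4+": 3
    },
    "quantitative": {
     "0/hpf": 0,
     "1-10/hpf": 1,
     "0-10/hpf": 1,
     "11-50/hpf": 2,
     ">50/hpf": 3
    }
   },
   "render": {
    "qualitative": [
     "none",
     "few",
     "moderate",
     "many"
    ],
    "semiquantitative": [
     "negative",
     "1+",
     "2+",
     "3+"
    ],
    "quantitative": [
     "0/hpf",
     "1-10/hpf",
     "11-50/hpf",
     ">50/hpf"
    ]
   }
  },
  "epithelial_cells": {
   "levels": [
    "none",
    "few",
    "moderate",
    "many"
   ],
   "dialects": {
    "qualitative": {
     "none": 0,
     "negative": 0,
     "neg": 0,
     "few": 1,
     "rare": 1,
     "moderate": 2,
     "many": 3,
     "loaded": 3
    },
    "semiquantitative": {
     "negative": 0,
     "1+": 1,
     "2+": 2,
     "3+": 3,
     "4+": 3
    },
    "quantitative": {
     "0/hpf": 0,
     "1-10/hpf": 1,
     "0-10/hpf": 1,
     "11-50/hpf": 2,
     ">50/hpf": 3
    }
   },
   "render": {
    "qualitative": [
     "none",
     "few",
     "moderate",
     "many"
    ],
    "semiquantitative": [
     "negative",
     "1+",
     "2+",
     "3+"
    ],
    "quantitative": [
     "0/hpf",
     "1-10/hpf",
     "11-50/hpf",
     ">50/hpf"
    ]
   }
  },
  "white_blood_cells": {
   "levels": [
    "none",
    "few",
    "moderate",
    "many"
   ],
   "dialects": {
    "qualitative": {
     "none": 0,
     "negative": 0,
     "neg": 0,
     "few": 1,
     "rare": 1,
     "moderate": 2,
     "many": 3,
     "loaded": 3
    },
    "semiquantitative": {
     "negative": 0,
     "1+": 1,
     "2+": 2,
     "3+": 3,
     "4+": 3
    },
    "quantitative": {
     "0/hpf": 0,
     "1-10/hpf": 1,
     "0-10/hpf": 1,
     "11-50/hpf": 2,
     ">50/hpf": 3
    }
   },
   "render": {
    "qualitative": [
     "none",
     "few",
     "moderate",
     "many"
    ],
    "semiquantitative": [
     "negative",
     "1+",
     "2+",
     "3+"
    ],
    "quantitative": [
     "0/hpf",
     "1-10/hpf",
     "11-50/hpf",
     ">50/hpf"
    ]
   }
  }
 }
}
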