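patient_id,diagnosis,age_years,previous_treatment_lines,sample_type,cell_markers,treatment,overall_response,pfs_weeks,ongoing_response
1,B-cell acute lymphoblastic leukaemia,23,5,Peripheral blood,"CD10, CD34",Bortezomib,Partial response,5.3,No
2,Diffuse large B-cell lymphoma,69,7,Dissociated lymph node,CD20,Ibrutinib,Complete remission,42.0,No
3,Precursor B-cell lymphoblastic lymphoma,51,3,Pleural effusion,"CD19, CD20","Obinutuzumab, 6-mercaptopurine, bortezomib",Partial response,12.9,No
4,Peripheral T-cell lymphoma,56,4,Bone marrow,CD3,"Ixazomib, lenalidomide, dexamethasone",Complete remission,22.6,No
5,Diffuse large B-cell lymphoma,29,2,Dissociated lymph node,CD79a,"Bortezomib, cladribine, dexamethasone",Complete remission,34.0,Yes
6,B-cell acute lymphoblastic leukaemia,29,2,Peripheral blood,"CD20, CD34","Bortezomib, azacitidine",Complete remission,37.1,Yes
7,Diffuse large B-cell lymphoma,60,5,Dissociated lymph node,"CD19, CD20","Imatinib, ibrutinib, lenalidomide, obinutuzumab; fludarabine, cyclophosphamide",Stable disease,37.3,Yes
8,Acute myeloid leukaemia,72,2,Peripheral blood,"CD34, CD117",Azacitidine,Complete remission,22.4,No
9,Primary mediastinal large B-cell lymphoma,27,6,Dissociated lymph node,"CD20, CD30, CD79a","Brentuximab vedotin, cladribine",Complete remission,34.7,Yes
10,T-cell lymphoblastic lymphoma,31,4,Peripheral blood,CD3,"Bortezomib, cyclophosphamide, dexamethasone",Partial response,4.1,No
11,Acute myeloid leukaemia,72,3,Peripheral blood,"CD34, CD117",Decitabine,Partial response,8.4,No
12,Diffuse large B-cell lymphoma,67,3,Lymph node,"CD20, CD79a",Ibrutinib,Complete remission,21.9,Yes
13,Follicular lymphoma grade 3A,63,3,Skin biopsy,"CD19, CD20, CD79a","Bortezomib, cladribine, dexamethasone",Complete remission,19.3,Yes
14,T-cell prolymphocytic leukaemia,40,2,Peripheral blood,CD3,Venetoclax,Partial response,13.9,No
15,Acute myeloid leukaemia,76,4,Bone marrow,"CD34, CD117",Azacitidine,Partial response,3.6,Yes
16,Diffuse large B-cell lymphoma,53,3,Dissociated lymph node,"CD19, CD79a","Pixantrone, idelalisib, obinutuzumab",Partial response,7.4,Yes
17,Diffuse large B-cell lymphoma,50,3,Bone marrow,"CD19, CD20, CD79a","Azacitidine, panobinostat, atorvastatin",Stable disease,3.3,No
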