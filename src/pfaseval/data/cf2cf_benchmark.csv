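entry_id,ligand_id,release_date,af3_backbone,af3_pocket,af3_ligand,af3_pocket_aligned_ligand,vina_ligand,vina_pocket_aligned_ligand,multiple_ligands
3RZ7_RZ7,RZ7,2011-08-10,0.02,0.01,0.04,0.06,0.19,0.68,false
3RZ1_RZ1,RZ1,2011-08-10,0.02,0.01,0.09,0.10,0.21,0.59,false
3RYZ_RYZ,RYZ,2011-08-10,0.03,0.01,0.06,0.07,0.16,0.18,false
3RYX_RYX,RYX,2011-08-10,0.02,0.01,0.11,0.11,0.18,0.41,false
4E99_P8S,P8S,2012-06-06,0.14,0.06,0.14,0.16,0.19,0.21,true
4J03_FVS,FVS,2013-06-05,0.08,0.05,0.27,0.45,0.27,0.49,false
5DDF_5A1,5A1,2015-09-09,0.11,0.02,0.12,0.13,0.17,0.95,false
6VQF_R7V,R7V,2020-04-08,0.35,0.18,0.07,0.08,0.12,0.14,false
6RZX_KPQ,KPQ,2020-06-03,0.02,0.01,0.02,0.03,0.03,0.27,false
7JTM_VK7,VK7,2020-09-16,0.36,0.23,0.09,0.11,0.09,0.11,false
7JYM_Z8I,Z8I,2020-11-25,0.26,0.15,0.06,0.07,0.12,0.16,false
7AAI_8PF,8PF,2021-02-24,0.44,0.08,0.14,0.87,0.17,0.91,true
7LUK_YDY,YDY,2021-05-12,0.45,0.22,0.09,0.13,0.12,0.17,false
7FD7_4EI,4EI,2022-07-20,0.03,0.03,0.13,0.48,0.15,0.43,true
7FEK_8PF,8PF,2022-07-27,0.03,0.02,0.17,0.30,0.18,0.57,true
7FEU_4I6,4I6,2022-07-27,0.03,0.02,0.12,0.13,0.15,0.48,false
7Z57_IGB,IGB,2022-10-12,0.46,0.10,0.13,0.22,0.14,0.28,true
8U57_8PF,8PF,2024-07-24,0.54,0.22,0.16,0.80,0.16,0.83,true
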